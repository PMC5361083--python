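# Default grouping of mental-health subreddits into 11 condition themes.
# Theme order is significant: it fixes the class indices used by the
# multiclass classifiers and every persisted report.
# The Aspergers subreddit is deliberately absent (post content was found to
# be only distantly condition-related, so it is excluded from the gold set).
themes:
  - name: BPD
    subreddits: [BPD]
  - name: bipolar
    subreddits: [BipolarSOs, BipolarReddit, bipolar]
  - name: schizophrenia
    subreddits: [schizophrenia]
  - name: Anxiety
    subreddits: [Anxiety]
  - name: depression
    subreddits: [depression]
  - name: selfharm
    subreddits: [selfharm, StopSelfHarm]
  - name: SuicideWatch
    subreddits: [SuicideWatch]
  - name: addiction
    subreddits: [addiction]
  - name: cripplingalcoholism
    subreddits: [cripplingalcoholism]
  - name: Opiates
    subreddits: [OpiatesRecovery, opiates]
  - name: autism
    subreddits: [autism]
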