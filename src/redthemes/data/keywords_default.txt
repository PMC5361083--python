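# Small illustrative keyword list for subreddit discovery (one lowercase
# whole-token term per line, '#' starts a comment). Curated clinical keyword
# lists are external resources; supply your own with --keywords for real use.
depression
depressed
anxiety
anxious
bipolar
mania
manic
schizophrenia
psychosis
suicide
suicidal
selfharm
cutting
overdose
addiction
addicted
relapse
withdrawal
opiate
opiates
heroin
alcoholic
alcoholism
drinking
autism
autistic
bpd
therapy
therapist
antidepressant
medication
meds
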