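# Methods

`redthemes` implements a two-stage text-classification study for
mental-health content in Reddit-style corpora: a binary task (is a post
mental-health-related at all?) and an 11-way task (which disorder theme
does a related post belong to?), together with the cohort construction,
topic-model validation and ranked evaluation that surround the
classifiers. This note records the models, the parameters that matter, the
synthetic data the package is tested on, and the design decisions taken
where the design was genuinely open.

## Cohort construction

Posts are labeled by their subreddit through a fixed subreddit → theme map
(11 themes; several themes pool multiple subreddits, e.g. *bipolar* ←
{BipolarSOs, BipolarReddit, bipolar}). The map is shipped as YAML and its
theme order fixes the class indices of every downstream artifact.
Subreddit matching is case-sensitive and exact, since Reddit names are
canonical; silently merging `Anxiety` and `anxiety` would be wrong.

The control (non-mental-health) stream is built with an index-date rule
from case-control epidemiology. An author's *index date* is the timestamp
of their earliest post in any mapped mental-health subreddit. Their posts
in unmapped subreddits qualify as controls only when dated at least
`window_days` (default 180) before the index date; the boundary is
inclusive (exactly 180 days qualifies), which is the literal reading of
"at least". All day arithmetic is `days x 86400` on integer UTC epoch
seconds — no timezone or calendar ambiguity. Authors with no mental-health
posts contribute no controls: control text comes from the same author pool,
which deliberately makes the binary task harder than an unrelated-corpus
control would be.

Subreddit discovery scores each subreddit by the fraction of its posts
whose lowercased title+body contains at least one keyword as a whole
token. The package ships a small illustrative keyword list; curated
clinical lists are external resources the user supplies.

## Text encoding

One fixed scheme feeds all four classifiers: title and body are
concatenated (title first), lowercased, and tokenized as maximal runs of
letters/digits with internal apostrophes kept ("don't" is one token). The
vocabulary is the 5,000 most frequent words of the **training split only**
(ties broken lexicographically), mapped to indices 1..5000; 0 is padding
and 5001 the single out-of-vocabulary integer. Each post becomes its first
300 token indices, end-padded with 0. End-padding keeps token positions
aligned with post openings, where the descriptive, condition-specific
content concentrates. Stopwords are deliberately *kept* for
classification; they are removed only for topic modelling.

## Classifiers

Four classifiers consume the same encoded posts:

* **FF** — embedding(16) → flatten → dropout(0.25) → dense(64, ReLU) →
  softmax.
* **CNN** — embedding(16) → 1-D convolution (64 filters, length 5, ReLU) →
  max-pool(2) → flatten → dropout(0.25) → dense(256, ReLU) → softmax.
* **linear** — multinomial logistic regression on term-frequency
  bag-of-words over the same vocabulary (scikit-learn, lbfgs).
* **svm** — linear-kernel SVM on the same bag-of-words (scikit-learn
  LinearSVC); decision values are mapped through a softmax, a monotone
  calibration that yields a probability-like ranking without claiming
  calibrated probabilities.

The bag-of-words for the baselines is computed from the same truncated,
padded sequences the networks see, so no classifier receives text another
lacks. The neural models are implemented as a compact numpy engine
(explicit forward/backward passes, verified against finite differences in
the test suite). Training minimises categorical cross-entropy with Adam
(lr 1e-3, batch 128, seeded Glorot/uniform initialisation), for at most
100 epochs with early stopping: a 10% slice of the training split is held
out for validation, and training stops after 5 consecutive epochs without
a validation-loss decrease, restoring the best-epoch weights. "No
improvement of the objective" is read as no decrease of validation loss
because the literal reading (no increase) never triggers. The convolution
filter length is 5 with max-pooling 2; both are exposed as configuration
knobs. The filter count (64), optimizer, learning rate and batch size are
not dictated by the architecture description and were fixed once at the
conventional desk-scale values above; they are recorded in each training
log.

## Evaluation

Confusion matrices use rows = actual, columns = predicted, in the fixed
class order. Per-class precision is column-wise, recall row-wise, and the
F-measure their harmonic mean; zero denominators report 0 with a warning
flag rather than NaN. The "weighted average" is support-weighted (each
class weighted by its true-instance count), which makes weighted recall
identical to accuracy — a useful internal consistency check. The Mean
Reciprocal Rank is

    MRR = (1/|P|) Σ_i 1 / rank_i

where `rank_i` is the 1-based position of post *i*'s true class when
classes are sorted by descending predicted probability, ties broken by
ascending class index (the same convention as argmax prediction, so a
correct prediction always has rank 1 and MRR ≥ accuracy, with equality iff
every correct class ranks first). Splits are simple seeded random 80/20
partitions; the identical split and encoding are reused by all four
classifiers within a task. Reports round percentages and ratios to two
decimals.

The class-ablation experiment removes every post of one class, re-derives
the class order, and reruns the identical split/train/evaluate stages; the
quantity of interest is the change in held-out accuracy on the remaining
classes.

## Synthetic corpora

The generator produces the statistical skeleton the analysis depends on,
and nothing more — no grammar, no discourse. Each theme is a Zipf(s = 1.3)
word distribution over its own vocabulary (default 350 types; background
1,200 types). A pair of themes with overlap *o* shares a fraction *o* of
their vocabulary types, and the shared types occupy the high-frequency
core of both distributions: two related communities share their frequent
jargon while the distinguishing terms sit in the rarer tail. This is what
makes a strongly overlapping pair genuinely confusable post-by-post — with
overlap 0.5, roughly 4% of a post's theme tokens are distinguishing, so a
small minority of posts carry little or no class-specific evidence, and a
trained classifier's confusion concentrates on the planted pair while the
type-level overlap measured on emitted text still matches *o*.

Each theme post mixes theme draws with a common background distribution
(default 30% background per token); control posts are pure background.
Document lengths are negative-binomial (mean 120 tokens, dispersion 2,
minimum 5) — heavy-tailed like real posts; the first five tokens become
the title. Each author writes a Geometric(1/2)-distributed number of posts
(support ≥ 1, mean 2). Theme posts get uniform timestamps over a fixed
two-year window. Control posts are written by a configurable fraction of
the theme authors (default 1.0, since the index-date construction only
retains controls by authors who also post in themes; lower values model
unlinkable throwaway accounts) and sit exactly `control_time_offset_days`
(default 200) before the author's earliest theme post, so the 180-day
filter has a known pass/fail structure.

The standard study conditions (`default_config`) are 11 themes of 1,000
posts named after the default theme map, vocabulary overlap 0.5 between
the two substance-addiction themes (Opiates and cripplingalcoholism), and
10,000 control posts — giving a roughly 52/48 mental/control binary task.
At these sizes the corpus lexicon (≈4.9k types) sits inside the 5,000-word
vocabulary cut, mirroring the regime where the cut covers nearly all
tokens. The ablation conditions (`ablation_config`) instead plant
depression as a dominant, broadly comorbid class: 1,600 posts vs 400 for
the other themes, a 900-type vocabulary, and 50% vocabulary overlap with
each of five related themes, so the related themes write mostly in
language depression also uses and their posts are systematically drawn
into the bigger class. Sizes were chosen so the full pipeline runs in
minutes on one CPU.

**What passing tests on this data do and do not show.** The generator's
posts are i.i.d. token mixtures: word *order* carries no class signal, all
class evidence is in token counts, and the Bayes classifier is linear in
the bag-of-words. Success here validates the pipeline's plumbing,
encoding, training loop and metrics — not any claim that convolutional
features beat linear models on real language, where compositional and
ordering signal exists. Accuracies on synthetic data are far above those
achievable on real social-media text and should not be compared to them.

## Topic-model validation

Theme cohesion is checked by fitting a 10-topic Latent Dirichlet
Allocation model per theme (scikit-learn implementation, seeded, other
parameters at their defaults and recorded in the result metadata) on
lowercased, tokenized, stopword-filtered posts, pooling all subreddits of
the theme; the same title+body concatenation is reused. The stopword list
is a standard English list shipped frozen in the package so results do not
drift with library versions. Reported topics are the 10 highest-weight
words each, ties broken lexicographically. On synthetic themes built from
planted disjoint word sets, the fitted topics recover each set as a
near-pure topic.

## Degenerate inputs and numerical conventions

Empty titles/bodies tokenize to the empty list and encode to all-padding
sequences, which every classifier accepts. Records missing author or
timestamp are skipped (and counted) at read time, since the control
construction needs both. All-zero confusion matrices are rejected;
zero-denominator metrics report 0 with a warning. Probability rows are
validated to sum to 1 within 1e-6. Every stochastic component — generator,
splits, network initialisation and shuffling, dropout, LDA — is driven by
an explicit integer seed, and reruns with the same configuration are
bit-reproducible on a platform.

## Known limitations

* The generator's i.i.d. mixture posts cannot express ordering signal, so
  deep-vs-linear comparisons on it are uninformative about real text (see
  above).
* Author behaviour is simplistic: no cross-theme authors, no activity
  bursts, no account churn beyond the overlap fraction.
* The ablation effect competes with the loss of training data from
  removing the dominant class; it only shows at desk scale when the
  dominant class is planted as broadly comorbid (high overlap with several
  themes), which is how `ablation_config` is built.
* Topic-count selection (scaling topics with corpus size) is out of scope;
  the topic stage validates cohesion, it does not optimise coherence.
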