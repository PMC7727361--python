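# Methods

This note records the models the package implements, the knobs that matter,
what the synthetic corpus does and does not emulate, and the numerical and
design choices made where the design was genuinely open.

## Screening models

**RCT vs non-RCT.** The screener is an ensemble of one max-margin
bag-of-words member and `n_cnn` convolutional members (10 in the production
configuration, 2 in the test configuration; the count is recorded in the
model metadata). The linear member is a linear SVM over TF-IDF
unigrams+bigrams with a held-out sigmoid (Platt) link so that it emits
probabilities; each convolutional member is a small word-embedding →
1-D convolution (window 3, 32 filters) → ReLU → max-over-time →
logistic network trained with Adam, differing from its siblings only by
initialization seed. Members are combined by the unweighted mean of their
probabilities — the combination rule was an open choice; the mean is the
simplest exchangeable rule and makes the ensemble permutation-invariant in
member order.

The convolutional members are implemented directly in numpy with manual
backpropagation. They are deliberately small: sized for corpora of a few
thousand templated abstracts, not for production biomedical text.

**Publication-type feature.** Records that already carry a manually applied
publication type contribute a three-valued indicator (tagged-RCT /
tagged-other / untagged), appended to the TF-IDF matrix for the linear
member and to the pooled feature vector for the convolutional members.
Because this feature shifts the score distribution, two balanced thresholds
are stored — one calibrated on indexed records, one on not-yet-indexed
records — and prediction picks the threshold matching the record's indexing
state.

**Balanced threshold.** `select_balanced_threshold` scans candidate cuts
(the minimum score, midpoints between consecutive distinct scores, and one
cut above the maximum) and returns the cut maximizing sensitivity +
specificity under the rule *score ≥ cut*. Ties are broken toward the
largest cut, i.e. toward precision: the screener feeds a fully automatic
pipeline with no manual screening step behind it, so among equally balanced
operating points the more conservative one is preferred. Returning the
midpoint between distinct scores (rather than an observed score) makes the
chosen cut stable under infinitesimal score perturbation.

**Threshold stability.** `bootstrap_threshold_stability` repeats, per
iteration: resample records with replacement, fit the balanced threshold on
the resample, evaluate precision and recall on the out-of-bag records.
Iterations with a one-class resample, an empty out-of-bag set, or an
out-of-bag set with no positives are redrawn. Intervals are 2.5/97.5
percentiles. The default 5000 iterations match the scale used for
production threshold evaluation; tests use far fewer.

**Human vs non-human.** A single calibrated linear SVM, thresholded at 0.5.
Training labels default to presence of the "Humans" indexing term, the
same label function used to build the original training resource; for
synthetic corpora the generator truth can be passed explicitly.

## Sample-size extraction

Number-word normalization parses maximal runs of cardinal words (units,
teens, tens with optional hyphenated units, "hundred", "thousand", with
"and" accepted only after hundred/thousand) and rewrites them as numerals,
keeping a segment-level offset map back to the original text. Parsing is
capped at 0–999 999; anything that does not parse is left verbatim, as are
ordinals, fractions, and a bare "one" directly before "of" ("one of the
arms"), which is a determiner-like use. Normalization is idempotent because
numerals are not number words.

Candidates are the integer tokens of the normalized text, excluding
integers immediately followed by "%" or preceded by a decimal point (these
are rates and decimal fragments, never counts of people). Each candidate's
feature vector concatenates:

- dense vectors (default 16-d) of the previous and next tokens, learned
  from the training corpus itself by positive-PMI co-occurrence
  factorization (truncated SVD), so no external embedding resource is
  needed; dimensionality is configurable;
- coarse part-of-speech one-hots of the previous and next tokens from a
  small rule-based tagger (closed-class lexicons plus suffix heuristics);
- indicators: a "patients"-variant token nearby, a randomization verb
  within 5 tokens, percent context, the 1900–2099 year range, month or
  parenthesis adjacency, and log1p(value)/10.

The "patients"-variant window looks 3 tokens ahead of the candidate plus
the single token behind it, not symmetrically ±3: counts precede the noun
they quantify ("112 patients"), and a symmetric window would fire on
following distractors such as "patients ... for 12 weeks". Year-like
integers get an indicator rather than being excluded, so small trials named
after years are not hard errors — the model learns the distinction.

The scorer is a one-hidden-layer feed-forward network (32 units). The
decision threshold is tuned on a held-out fifth of the training corpus to
maximize abstract-level extraction F1. At prediction time the
highest-probability candidate wins, ties broken toward the larger integer
(the total randomized is usually the largest count in a randomization
sentence); if nothing clears the threshold the extraction is absent.
Registry records skip all of this and return the target-sample-size field
directly.

## PICO tagging and concept linking

**Span tagger.** Token-level BIO labeling over three facets (7 labels).
The tagger is an averaged structured perceptron over lexical context
features (current/±1/±2 lowercased words, two bigrams, prefix/suffix,
shape) with a learned transition matrix and Viterbi decoding constrained to
BIO-consistent paths (no I-x after anything but B-x/I-x, none at sentence
start). A feature-based linear-chain model was chosen over a recurrent
encoder as the package's sequence labeler: it is exactly decodable,
deterministic, dependency-free, and more than sufficient for the templated
corpora this package trains on; the module boundary (`train_span_tagger` /
`tag_spans`) leaves room to swap in a neural encoder. Averaging needs a few
epochs to wash out early updates — 6 epochs for corpus-scale training,
more (≈50) to memorize a single abstract.

Decoded label runs are converted to character spans via the token offset
table; spans never overlap within a facet by construction of the decoder.

**Abbreviation expansion.** Definitions are located anywhere in the
abstract as a parenthesized short form (2–10 characters, at least one
uppercase letter, starting with a letter) immediately preceded by its long
form. The long form is the shortest suffix of the preceding words, at most
min(|SF|+5, 2·|SF|) words, whose first word starts with the short form's
first character and which contains all short-form characters in order.
Bare short-form mentions inside a snippet are then replaced by the long
form before dictionary lookup. Texts without parentheses are untouched.

**Synonym index and linking.** Every vocabulary synonym is normalized —
one trailing bracket group stripped (generalizing the "[NOS]"-style
database tags), lowercased, whitespace collapsed — and indexed by token
sequence; a synonym shared by several concepts retrieves all of them
(recall-oriented). Linking scans the expanded snippet
longest-match-first and non-overlapping, so "anterior wall myocardial
infarction" yields only the specific concept, not its nested parents.
Strict evaluation counts exact concept-id matches; relaxed evaluation also
accepts immediate parents and children (no transitive closure). Both are
micro-averaged with record-level percentile-bootstrap intervals. By
construction relaxed ≥ strict on every input.

When a tagged span set is empty, no concepts are emitted for that record —
linking happens only inside spans, never over the whole abstract.

## Risk of bias

`derive_overall` is the conjunction rule: low overall iff every rated
domain is low; high and unclear are merged into `not_low` because the
downstream use is ranking by P(low overall), not per-domain claims. The
classifier is logistic regression with L2 (ridge) penalty over
unigram+bigram+trigram counts of title+abstract, vocabulary pruned at
minimum document frequency 2 for memory; the inverse penalty C is selected
on a validation split by Brier score when not fixed. The 0.5 decision
threshold is reported for completeness, but the ranking pathway consumes
the raw probability — binary use of this signal is known to be weak, while
the calibrated probability ranks well. Evaluation reports precision/recall
at 0.5, Brier score, C-statistic (ties counted 1/2 per pair; computed by
the rank-sum identity and therefore invariant to strictly monotone score
transforms), and a 10-bin equal-width reliability table, each with
percentile-bootstrap intervals.

## Retrieval and ranking

Queries are conjunctive over (concept, facet) terms — the motivating use
case, "population X AND intervention Y", implies AND semantics — with
`any` matching a concept in any facet, plus published/registered filters.
Default order is recency (year descending, then record id) for the
surveillance use case. Quality ranking scores
`w_q · P(low bias) + w_n · log10(n)` with defaults `w_q=1, w_n=0.5`;
absent components contribute 0, and the log damps sample size so mega-trials
do not swamp methodological quality. The weights are configuration, not a
claim about any production system; re-ranking is a pure permutation of the
result set. Term suggestion matches normalized prefixes of preferred terms
and synonyms and pairs each concept with its modal facet in the store,
ordered by store frequency. The store itself is JSON-lines plus an
in-memory inverted index — adequate at desk scale and swappable behind the
`AnnotatedStore` interface.

## Synthetic corpus

The generator is the package's stand-in for the external training
resources (crowd-labeled screening corpora, expert PICO annotations,
registry dumps, licensed thesauri). It emulates, with exact gold offsets
recorded at construction time (never by post-hoc search):

- RCT abstracts with a randomization sentence embedding the sample size,
  drawn log-uniformly from (8, 600) — median ≈ 70, in line with published
  trials — rendered as number words for ~20% of records to exercise the
  normalizer in-line;
- population/intervention/outcome sentences realized from vocabulary
  synonyms; distractor integers (durations, years, ages, percentages) drawn
  distinct from the planted size; abbreviation definitions with later bare
  mentions for ~35% of eligible records;
- per-domain bias ratings (all-low with probability `low_bias_fraction`,
  default 0.3, roughly the share of trials rated low across all first-tool
  domains) and methods phrases included per domain with probability
  sigmoid(−1.8 + 3.4·[domain low]) — ≈0.83 when low, ≈0.14 otherwise —
  with the coefficients recorded in the corpus metadata so the planted
  signal is testable;
- non-RCT observational templates, non-human animal templates, a "Humans"
  indexing term on human records, and the RCT publication type applied to
  70% of RCTs by default (`ptype_index_rate`), modeling the indexing lag of
  real databases;
- registry entries with semi-structured design/size/PICO-snippet fields;
- a vocabulary whose concepts are partitioned across facets, with 1–4
  synonyms each (some bracket-tagged and case-varied) and modifier-based
  child concepts whose surface contains the parent term, exercising both
  longest-match linking and relaxed parent/child evaluation.

What it does **not** emulate: real linguistic variety (passives, anaphora,
reporting idioms), noisy or contradictory gold labels, class imbalance at
database scale (real RCT prevalence is 1–2%, the default corpus is 50%
for trainability), licensed vocabulary content, and abstracts where the
sample size is absent or only derivable by arithmetic. Passing tests
therefore demonstrate that each component recovers the structure it was
built to recover under clean conditions — correctness of the machinery,
not clinical-grade accuracy on real abstracts.

## Numerical conventions and degenerate inputs

- Character offsets are 0-based, half-open, over Unicode code points of the
  stored abstract; structured abstracts are joined with single spaces so
  offsets stay valid.
- Registry sample sizes parse only from bare-integer cells (ranges like
  "100-200" become absent rather than silently wrong).
- Metrics with zero denominators are reported absent (None), not NaN.
- Percentile bootstrap (not BCa), 95% level; a resample on which a
  statistic is undefined is redrawn up to 10 times, then the interval is
  reported absent. The point estimate is computed on the full data and is
  not guaranteed to lie inside the percentile interval.
- Empty-text records are scored, not rejected (logged); empty abstracts get
  the intercept-only bias probability.
- One-class inputs raise for training and threshold selection, and yield an
  absent C-statistic in evaluation.

## Problem sizes

Default test/recovery configurations: 1000-record mixed corpus (800 train /
200 test) for screening with 2 convolutional members; 1500-record all-RCT
corpus for extraction and bias (1000 train / 500 held out; tagger 800/200);
10 000-draw calibration streams; 100-instance oracle sweeps. These sizes
give stable estimates while keeping a full from-scratch rebuild of every
model in the tens of seconds on one CPU.
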