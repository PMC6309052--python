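# Methods

This document describes the model implemented by `recurrex`, the defaults
it ships, and the reasoning behind the implementation choices that the
published description of this class of pipeline leaves open.

## Problem

Classify each breast-cancer patient as having a **local recurrence**
(malignancy returning at the original site after lumpectomy, or in the
chest wall after mastectomy) or not, from two signals:

* the free-text progress notes written during follow-up, and
* the number of pathology reports generated long after the primary
  diagnosis (recurrence workups produce biopsies and surgical specimens).

Distant metastasis and contralateral disease are *not* local recurrence;
sentences describing them use nearly the same vocabulary, which is the
dominant failure mode (see "Confound design" below).

## Pipeline stages

### 1. Preprocessing (`corpus.py`)

* Notes are deduplicated per patient: two notes whose *normalized* texts
  are identical collapse to the earliest-dated one (clinical notes are
  frequently copy-forwarded).
* Sentences are split on runs of `.!?` followed by whitespace and an
  uppercase letter or digit (or end of text), after masking the periods of
  a configurable abbreviation list (`dr`, `pt`, `h/o`, …).
* Normalization lowercases, replaces every non-alphanumeric character with
  a space, and collapses whitespace. All downstream stages operate on this
  normalized form.

### 2. Concept tagging (`tagger.py`)

A dictionary tagger stands in for MetaMap behind a pluggable `Tagger`
protocol. Its contract:

* every whole-word occurrence of every lexicon surface form yields a
  mention; overlapping matches from different entries are all kept (one
  phrase may denote several concepts);
* when two CUIs claim the exact same character span, the higher-score CUI
  wins (the score column is the analogue of the MetaMap MMI relevance
  score), ties broken by lexicographically smallest CUI — this makes
  disambiguation deterministic and independent of lexicon row order;
* duplicate CUIs within one sentence collapse to their first occurrence.

### 3. Contextual filtering (`context.py`)

Two mechanisms, applied in a fixed order (the retained set is
order-independent; the order only fixes per-stage drop counts):

* **Sentence-level cues.** A sentence containing any negation cue stem
  (`no`, `rule out`, `deny`, `unremarkable`, …) or uncertainty cue stem
  (`risk`, `concern`, `worry`, `evaluation`, …) is dropped wholesale.
  This trades recall for precision: differential-diagnosis and
  patient-anxiety sentences mention recurrence without asserting it.
* **NegEx.** Within surviving sentences, a mention is removed when it lies
  within 6 tokens after a pre-trigger (`no evidence of …`) or 6 tokens
  before a post-trigger (`… was ruled out`), with the scope cut at
  terminators such as `but`.

**Stem matching.** Cue stems of ≥ 4 characters match as token prefixes
(`concern` fires on "concerned"); shorter stems must match a whole token,
so `no` does not fire on "now", "nodule", or "normal". The 4-character
floor (`MIN_PREFIX_STEM`) is an implementation decision: unrestricted
prefix matching makes 2–3 character stems fire on unrelated words, while
whole-token-only matching misses the inflections the stems are meant to
cover.

### 4. Positive concept set (`positive.py`)

The narrative features are gated by a 48-CUI whitelist. It is *derived*,
not hand-listed: 93 development sentence fragments describing recurrence
are tagged with the lexicon, the tagged CUIs are pooled, and a declarative
exclusion file removes function-word concepts — the reproducible analogue
of a manual curation step. `recurrex derive-positive` re-derives it, and a
test asserts the packaged set equals the derivation.

### 5. Features (`features.py`)

* **Power sets.** Per sentence, every non-empty subset of size ≤ 3 of the
  retained CUIs becomes one binary presence feature
  (`C(n,1)+C(n,2)+C(n,3)` keys). Single CUIs are ambiguous ("recurrent"
  alone does not imply local recurrence); pairs and triples restore the
  within-sentence context that makes them informative. Feature values are
  binary presence per patient — power sets are set-valued, and chi-square
  selection fits presence semantics.
* **Pathology count.** Reports dated ≥ 120 days (inclusive) after the
  primary diagnosis. It is the only non-binary feature.
* **Combinatorial guard.** Distinct CUIs per sentence are capped (default
  10, configurable) before expansion, with a warning; pathological
  sentences would otherwise expand cubically.

Baseline spaces: `full_concepts` = singleton keys for every
context-filtered CUI, no gate, no power sets; `filtered_concepts` = the
gated power sets without the count; `bag_of_words` = per-patient TF-IDF
(smoothed IDF, L2-normalized rows, via scikit-learn's `TfidfVectorizer`)
over raw note text. The full-concepts baseline keeps the negation
filtering (shared preprocessing).

### 6. Selection and classifier (`model.py`)

* **Chi-square selection.** Each binary feature is scored by the Pearson
  chi-square of its 2×2 contingency with the label (no continuity
  correction; hand-rolled closed form, tested against
  `scipy.stats.chi2_contingency(correction=False)`). The top
  `ceil(fraction · n)` features are kept (default fraction 0.5), ties
  broken by key order. The pathology count is exempt from the ranking and
  always retained: it is the one deliberately engineered non-categorical
  feature, and a 2×2 statistic is not defined for it.
* **Scaling.** The pathology-count column is standardized to zero mean and
  unit variance on training data before entering the kernel; binary
  features stay 0/1. An RBF kernel effectively requires the count to be on
  the same scale as the binary block.
* **Grid search.** Kernels (rbf, linear, poly, sigmoid) × C ∈ {1, 11, …,
  91} × gamma ∈ {0.0001, 0.0011, …, 0.0091}; gamma collapses to a single
  placeholder for the linear kernel. The winner maximizes mean
  micro-averaged F1 over stratified, seeded 5-fold cross-validation. (In
  binary single-label classification micro-F1 equals accuracy; it is
  computed as micro-F1 to keep the criterion explicit.) Ties go to the
  smaller C, then smaller gamma, then kernel order — again to make the
  outcome deterministic.
* **Probabilities.** Platt-style sigmoid calibration via
  `CalibratedClassifierCV(SVC(...), method="sigmoid", ensemble=False,
  cv=5)` — the same estimator scikit-learn's deprecated
  `SVC(probability=True)` delegates to, fitted on internal training folds.
  Classification uses the cutoff convention `score ≥ 0.5 → positive`.

### 7. Evaluation (`evaluate.py`)

* Seeded simple random 7:3 split (`round(0.7·n)` training patients,
  Python banker's rounding; not stratified — a simple random split may
  drift in class balance, and that is reported, not corrected).
* Metrics: confusion counts at the cutoff, precision/recall/F1 from the
  counts, midrank AUC (equivalent to the Mann–Whitney U formulation;
  undefined metrics are reported as `null`, single-class AUC with a
  warning). Cohen's kappa (marginal-product chance agreement) is provided
  for annotation-agreement computations.
* The experiment harness reports, per feature mode, fold-wise CV metrics
  (mean ± SD), one held-out evaluation, and paired t-tests across folds
  between the proposed model and each baseline. Error analysis lists every
  false positive/negative with its score, pathology count, and surviving
  sentence evidence, plus mean pathology counts per confusion cell.

## Synthetic corpus generator (`simulate.py`)

The real corpus is protected health data, so the generator reproduces the
*statistical structure* the pipeline assumes — not real clinical language:

* labels drawn at a configurable prevalence (default 0.2753, n = 701,
  mirroring the published double-annotated cohort);
* recurrence-positive patients receive ≥ 1 sentence from a positive
  template pool (suppressed at `positive_noise_rate`, modelling patients
  whose notes never state the recurrence);
* any patient may receive negated/uncertain recurrence sentences built
  from the *same content vocabulary* inside negated frames, which the
  contextual filter is expected to drop — and which keep a lexical
  bag-of-words baseline from separating the classes on vocabulary alone;
* at `confound_rate`, negative patients receive distant/contralateral
  recurrence phrasing that survives filtering (see below);
* per-patient qualifying pathology counts are negative-binomial with
  class-conditional means 4.55 (recurrent) and 0.92 (non-recurrent) and
  dispersion 1.0; a 0.7-probability early diagnostic biopsy before day 120
  checks the threshold logic;
* every note carries a unique header sentence so deduplication never
  silently merges sibling notes, and every inserted template is recorded
  in a trace with a `should_survive` flag that tests check against the
  actual filter output.

**Confound design.** The documented failure mode of a narrative
local-recurrence classifier is that distant and contralateral events are
*textually indistinguishable* from local ones — the site information is
simply absent from the sentence. The confound pool therefore reuses the
positive templates verbatim plus explicit contralateral/distant flavor
sentences, and confounded negatives draw their pathology counts from the
recurrent-class distribution (a contralateral cancer generates its own
biopsies and surgeries). Raising `confound_rate` consequently lowers
precision at the 0.5 cutoff — a directional effect the test suite asserts
at `positive_noise_rate = 0.15`, comparing `confound_rate` 0 vs 0.25 on
700-patient corpora.

**Scope and limits.** The generator emulates co-occurrence structure,
class-conditional counts, and filterable negation. It does not emulate
discourse structure, temporality across notes, misspellings, or section
headers; absolute metric values on synthetic corpora (AUCs near 1.0 at
zero noise) are therefore not comparable to values on real notes. Tests
assert *relative* and *directional* properties — proposed > bag of words,
confound lowers precision — not absolute reproduction.

## Numerical and reproducibility choices

* Chi-square, kappa, and the power-set expansion are hand-rolled closed
  forms, each tested against an independent oracle (scipy, scikit-learn,
  brute-force enumeration).
* AUC uses `sklearn.metrics.roc_auc_score` (midrank ties).
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`, seeded `StratifiedKFold`); reruns of the
  pipeline with an identical config produce byte-identical reports, and a
  test asserts it.
* Problem sizes used in the test suite: unit tests run on corpora of
  20–120 patients; the end-to-end signal-recovery and confound tests use
  700 patients with a reduced grid (2 kernels × 3 C × 3 gamma) and finish
  in seconds per experiment.
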