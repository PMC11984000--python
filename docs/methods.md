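# Methods

This note documents the models and procedures implemented in
`vidability`, the design decisions behind them, and what the synthetic
experiments do and do not demonstrate.

## Understandability scoring

An assessment is a 12-item vector over the audio/visual PEMAT
understandability items, each item 1 (agree), 0 (disagree), or — for the
seven items where the construct can be absent (chunked sections,
informative headers, summary, on-screen text readability, audio clarity,
illustrations, tables) — not applicable. Five items (purpose evident,
everyday language, medical terms defined, active voice, logical sequence)
are strictly 0/1. The score is the agreed fraction of applicable items,
×100; an all-N/A assessment is rejected (undefined denominator). The
high/low label uses a **strict** threshold: exactly 50.0 is *low*.

Percentages in summaries are computed exactly and rounded half-up to one
decimal (two for coverage figures) only for reporting; comparisons use
unrounded values.

The packaged reference campaign (700 diabetes patient-education videos)
is stored as per-item marginal counts plus the overall 315/385 low/high
split. The fixture builder reconstructs 700 assessments satisfying both:
items are packed row-wise and then repaired with marginal-preserving
swaps (moving a single item's 1 between two rows) until exactly 385 rows
derive a high label. Only marginals and the overall split are
constrained; the within-row joint distribution is otherwise an artifact
of the construction. The builder verifies the result at run time.

## Text features

No external NLP toolkit is required; the pipeline's text primitives are
small, deterministic, and fully documented:

* **Tokenizer.** Words are maximal alphanumeric runs optionally joined by
  apostrophes/hyphens; sentences split on `. ! ?` followed by whitespace
  or end of text. Deterministic and reproducible by design.
* **Readability.** ARI = 4.71·(letters/words) + 0.5·(words/sentences) −
  21.43 with letters-only character counts; Flesch-Kincaid grade =
  0.39·(words/sentences) + 11.8·(syllables/words) − 15.59 with a
  vowel-group syllable heuristic (consecutive vowels count once, a
  silent final "e" is dropped unless the word ends in "-le", minimum
  one). The syllable
  heuristic is approximate; the feature builders therefore default to ARI,
  with `FK_grade` selectable. Zero-word text has no defined score: the
  builders record the missing-value code (NaN), direct calls raise.
* **Active voice.** The count of tokens tagged VB, VBD, VBG, VBP, or VBZ;
  past participles (VBN) — the passive-realizing form — are excluded.
  Tagging is a pluggable contract (`tag(tokens) -> TaggedToken list`).
  The default is a small rule-based tagger (closed-class lexicon, a
  common-verb stem list, suffix rules) adequate for feature extraction;
  correctness of the counting rule itself is established against
  hand-tagged fixtures, and synthetic corpora ship their own exact tag
  maps.
* **Cue phrases.** Summary and transition lexicons are packaged as plain
  text (one lowercase phrase per line). Counting is case-insensitive at
  word boundaries, longest phrase first, non-overlapping, and never
  crosses a sentence boundary — which makes counts additive over
  sentence-separated concatenation. Phrases appearing on both lists
  ("finally", "thus", "hence", …) count toward each lexicon
  independently, since the two counts are separate features.
* **Medical terms.** A dictionary matcher over six category lexicons
  (body parts, chemicals/drugs, devices, events, professionals,
  procedures) using the same longest-first rule on the merged dictionary,
  so "insulin pen" is one device, not a drug plus a stray token. The packaged
  lists are deliberately small starters; any recognizer producing
  per-category counts can replace the matcher (the feature builders
  consume only the counts). Full terminology-base integration is out of
  scope.

Each view has exactly 12 named features in a fixed order. The metadata
view's purpose-evident construct is realized as has-title /
has-description / has-tags flags, with empty text treated as absent. An
empty description or transcript yields zero counts and NaN readability;
absent transcription/OCR confidences are NaN. Units without content
signals cannot supply the content view and are rejected by the content
builder — two-view analyses use only videos with both a description and a
narrative.

## Co-training

Given a labeled pool L (both classes required) and unlabeled pool U with
both views, each iteration: (1) fit F1 on the metadata view of L′ and F2
on the content view; (2) score U with both; (3) select confident
positives/negatives per view with an inclusive threshold t (p ≥ t, or
1−p ≥ t; t > 0.5 guarantees disjointness) — selections are
threshold-defined sets, not fixed-size draws; (4) cross-view agreements
are auto-labeled, confident cross-view conflicts are resolved by the
oracle, ids confident in only one view stay in U; (5) halt when U is
empty, nothing was added, or the iteration cap is reached. All oracle
answers for an iteration are collected before any labels are applied, so
an oracle failure aborts the iteration without partial mutation.

Parameters: confidence threshold 0.65 (dimensionless probability; the
value that converged well on real video corpora — lower thresholds buy
speed at the cost of more human arbitration and more label noise, higher
ones risk early stopping), iteration cap 50 (a safety bound; runs
converge far earlier), L2 strength 1.0.

The base learner is a pipeline: mean imputation of missing codes with
missingness indicators, per-view z-scoring from the current L′, then
L2-regularized logistic regression (chosen for interpretability; any
object with `fit` and a two-column `predict_proba` conforms). Final
predictions average the two views' positive probabilities with an
inclusive 0.5 decision boundary. Leftover unlabeled units at halt are
labeled by policy: `mean_probability_vote` (default) uses the combined
probability; `label_low` assigns low — the handling appropriate when
leftovers are known to be unclassifiable (e.g. foreign-language
narratives under English descriptions). Fallback labels are recorded in
L′ with provenance `fallback` but the final classifiers are trained
before fallback labeling, so they never learn from it.

Determinism: iteration order over ids is lexicographic, the simulated
oracle's error flips depend only on (seed, video id), and the audit log —
one entry per iteration with selections, agreements, conflicts, oracle
decisions, and optional held-out error — is fully determined by the
config seed. Seed labels can never be overwritten.

Metrics: per-class precision/recall/F1 with support-weighted aggregates;
AUC as the positive-outranks-negative probability (ties half); pooled and
per-query precision-at-K. Single-class truth leaves AUC undefined (None,
with a warning) while the other metrics are still returned.

## Engagement analysis

Treatment is the binary high-understandability label; outcomes are
natural-log engagement counts, log(count+1). Covariates: log channel
views+1, log subscribers+1, log channel video count (no +1; a +1 fallback
with a warning when zeros occur), an SD-definition flag (HD is the
reference level), duration in seconds, description word and unique-word
counts, and log days-since-publication+1.

* **CEM** (default): continuous covariates are coarsened into equal-width
  bins, Sturges' count on the observed range by default (binary and
  near-constant covariates keep their levels); units are stratified by
  joint bin signature; strata lacking either group are dropped; treated
  weights are 1 and control weights (m_T/m_C)·(M_C/M_T) within each
  stratum, so each group's weighted total equals its retained count. The
  result is a variable-ratio matched sample.
* **PSM**: logistic propensity (constant covariates dropped from the
  design; an all-constant design reduces to the treated fraction;
  complete separation is detected per covariate and reported by name),
  then greedy 1:1 nearest-neighbor matching on the logit without
  replacement, caliper 0.2 SD of the logit, ties and iteration order
  broken lexicographically by id.

Balance: SMD = (weighted treated mean − weighted control mean) / the
unweighted sample SD of the **full treated group**, so before/after
values share a denominator and are comparable. A zero treated SD with
unequal means yields a signed-infinity sentinel and a warning.

The ATE is the treatment coefficient of a weighted least squares fit of
the log outcome on intercept + treatment over the matched sample only.
No covariate adjustment is added on top of matching, and no
matching-uncertainty correction is applied to the standard errors —
within-stratum residual confounding at bin resolution is the known
residual bias of CEM.

Both CEM and PSM are provided deliberately: variable-ratio matched group
sizes arise naturally under CEM, while a propensity model supports
PSM-style workflows; the package exposes both rather than privileging
one.

## Synthetic corpora

`generate_corpus` realizes the two-view assumption directly: a Bernoulli
label (prevalence 0.55 by default) drives class-conditional Gaussian
settings for every planted quantity, independently across views given the
label (verified empirically: within-class cross-view correlations ≈ 0).
High-understandability videos get more cue phrases and active verbs,
fewer medical terms, shorter texts and durations, fewer scenes, and
higher transcription/OCR confidences; the default class-mean separation
is 2 within-class SDs per feature — the "separable" regime. Texts are
assembled from filler sentences verified free of every packaged lexicon
phrase, with planted phrases/verbs/terms inserted as whole sentences, so
extraction recovers the planted counts exactly (a property the suite
tests across random specs). Channel statistics, publication age, and
definition flags are driven by a latent maturity variable u ~ U(0,1);
engagement follows log(count+1) = α + τ·label + β·(2u−1) + ε with
α = (8.9, 3.2, 1.6) for views/likes/comments, τ = 2.5, β = 2, ε ~ N(0,1)
by default, rounded to nonnegative counts.

Because the corpus generator makes duration and description length
*label-driven* (they are content properties), they would be mediators in
a causal analysis of that corpus. Estimator validation therefore uses
`generate_causal_units`, where every matching covariate is a monotone
function of u with small independent noise (pre-treatment by
construction), treatment probability is sigmoid(logit(0.45) + 1.8·(2u−1))
when confounding is on, and outcomes follow the same log-linear model.
The single-confounder design keeps bin signatures effectively
one-dimensional, so CEM retains a large matched sample; it is the
standard simulation design for matching estimators, not a claim about
real platforms.

Problem sizes in the test suite and acceptance script: co-training uses
60 seed-labeled + 600 unlabeled + 200 held-out videos; effect recovery
uses n = 2000 with τ = 2.5; the null-coverage check uses 100 replicates
of n = 400. These sizes give stable verdicts for the properties tested
(3-SE recovery bands, ≥90/100 nominal-95% coverage) while keeping the
whole suite inside a few seconds.

**What passing these tests shows — and does not.** The synthetic corpus
demonstrates that the machinery is correct: exact feature round-trips,
co-training that propagates labels and consults the oracle only on
cross-view conflicts, matching that removes planted confounding. It does
not emulate real platform text, real ASR/OCR error processes, label
noise, or view correlations; real-corpus performance (where weighted F1
near 0.8, not 1.0, is typical) depends on those properties and on expert
label quality, none of which the generator models.

## Known limitations

* The medical-term dictionary is a starter; serious use should plug in a
  trained recognizer via the recognizer contract.
* The default POS tagger is heuristic; supply a dictionary or external
  tagger for production-quality active-voice counts.
* Matching standard errors ignore the uncertainty induced by the matching
  step itself; doubly-robust or IPW estimators are out of scope.
* PEMAT actionability (as opposed to understandability) is not scored.
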