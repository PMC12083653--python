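# Methods

## Label model

Marital status is a closed eight-class vocabulary: `MARRIED`, `SINGLE`,
`PARTNERED`, `DATING`, `SEPARATED`, `DIVORCED`, `WIDOWED`, `NOT_GIVEN`.
`DATING` is derived, never emitted by a base annotator: a `PARTNERED`
prediction without cohabitation evidence is either demoted to `SINGLE`
(first-stage harmonization, `recode_partnered`) or routed to `DATING`
(`derive_dating`). An `ENGAGED` class is deliberately absent — engaged
patients are too rare to estimate and are folded into the partner spectrum.
Living arrangement is `ALONE` / `WITH_FAMILY` / `WITH_OTHERS` /
`NOT_GIVEN`; cohabitation with a partner is a separate three-valued signal
(`WITH_PARTNER` / `NOT_WITH_PARTNER` / `UNKNOWN`) because "lives with
family" does not imply living with a partner.

`NOT_GIVEN` plays two roles that the code keeps distinct: a *genuine* label
(the note states nothing) and an *abstention fallback* (voters disagree).
Ensemble decisions carry an explicit `abstained` flag so that
pseudo-labeling can drop fallbacks while keeping genuinely-agreed
`NOT_GIVEN` as a class.

## Ensembles

The vote record has five categorical features: three marital votes
(structured field, model A, model B) and two living votes (model A, B).

* Unanimous and majority voting need no tuning data. `NOT_GIVEN` counts as
  an ordinary vote value: two annotators agreeing on `NOT_GIVEN` is a
  majority, not an abstention.
* The precision-based rule is interpreted **per predicted class**: among
  the three (annotator, predicted-label) pairs, follow the cell with the
  highest tuning-split precision. A single-globally-best-model reading
  would collapse the ensemble onto one annotator and could never beat all
  three; it remains available as `precision_select_global`. Undefined cells
  (a class the annotator never predicted on the tuning split) enter the
  argmax as 0 — a never-validated prediction is never trusted. Exact ties
  resolve by fixed priority model A > model B > structured field, the
  descending order of typical individual-model quality.
* The forest strategy uses 200 bagged trees, depth ≤ 8, per-split feature
  subsampling over one-of-K encodings, fixed seed. No hyperparameters are
  load-bearing; these are conventional, cheap defaults. Unseen feature
  levels encode as all-zero blocks rather than errors.

## Weak supervision

The student is a bag-of-ngrams (lowercase alphanumeric unigrams + adjacent
bigrams, term frequency) multinomial logistic classifier. The objective is
the per-sample-averaged log-loss with an L2 penalty (default λ = 1e-3,
tolerance 1e-6, ≤ 500 iterations), minimized by a deterministic full-batch
quasi-Newton solver (lbfgs). Averaging the loss — implemented by setting
the sklearn `C` to `1/(λ·n)` — makes the fit invariant to duplicating the
pool, which is the natural scaling for pseudo-labeled data of arbitrary
volume. Heavier encoders can be slotted behind the same text→label
interface; the mechanism under test (pseudo-label, drop abstentions, fit a
text model, recover recall) does not depend on the encoder.

Abstention-derived `NOT_GIVEN` pseudo-labels are excluded from training by
default (config-selectable), since they encode "the teacher could not
decide", not "the note gives no status".

## Evaluation conventions

Per-class precision/recall/F1 with support; macro = unweighted mean over
classes with nonzero gold support (zero-support classes stay in the report,
flagged; a config flag includes them in the macro mean); weighted =
support-weighted mean; accuracy = confusion-matrix trace / total. Weighted
recall equals accuracy algebraically; the suite fuzz-tests the identity.
`NOT_GIVEN` is scored as an ordinary class.

## Synthetic data

**Corpus.** Each note is a social-history snippet assembled from a marital
cue sentence (≥ 3 templates per class), an optional living-arrangement
sentence, and cue-free substance-use filler. Templates are cue-faithful: a
note for class *s* matches only *s*'s cue lexicon, which makes the pattern
annotator's 100% ceiling on noise-free text a testable property, and a
`cue_noise_rate` knob replaces cue sentences with filler to degrade it
gradually. The default class mix follows the annotated tuning-split
composition (single 53, partnered 49, married 117, separated 6, divorced
34, widowed 42, not given 21, of 322). The structured field stores the
token of the gold status (`LIFE PARTNER` for partnered; dating patients are
filed under `SINGLE`, mirroring how demographic fields actually behave),
except: missing (empty) with probability 0.10 and stale — the token of a
uniformly chosen *other* status — with probability 0.10.

**Cohort.** Patients carry Gaussian ages (mean 57, SD 12, clipped to
[18, 95]), 1 + Poisson(1.3) admissions with inter-admission gaps uniform on
[0.5, 6] years (so the 5-year eligibility filter actually bites), a
status path drawn either from a persistent Markov transition matrix (0.96
self-transition) or — in stratified mode — constructed to realize exact
same / got-married / other-change group sizes (defaults 2500 / 40 / 99),
and an integer E-VW comorbidity score, Poisson with mean 5 for married, 7
for divorced, 6 otherwise (reproducing the published median contrast).
Condition flags are parameterized directly by the quantities the estimators
measure: per change-group incidence probabilities (change group: 7.2% /
4.3% / 7.2% for depression / alcohol / drug; stable group: 6.2% / 1.4% /
1.6%) and recovery probabilities (10.8% / 5.0% / 5.8% vs 4.2% / 1.8% /
1.6%), with the residual constant-flag probability solved so the
first-admission marginal matches the per-status prevalence (married
depression 9.32%, etc.). Prevalence cells without a published point
estimate (e.g. single/divorced depression) are declared package defaults at
plausible mid values. Admission-gap distribution and age SD are likewise
declared choices — no source states them.

**What passing tests do and do not show.** The generator produces exactly
the structure the estimators assume: conditionally independent annotator
errors, cue-separable text, parametric flag dynamics. Passing tests
validate the *machinery* — aggregation rules, estimators, intervals,
plumbing — not performance on real clinical notes, where annotator errors
correlate, negation and temporality matter, and cue lexicons leak across
classes.

## Numerical choices

* Exact binomial CIs are Clopper–Pearson from Beta quantiles; lower bound 0
  at x = 0, upper bound 1 at x = n. Percentages are reported to one
  decimal, half-up. Event counts for validation against published rates are
  reconstructed as round(rate × n). Clopper–Pearson was fixed after
  checking that it reproduces all six published change-cohort bounds at
  n = 139 to one decimal percent, which Wald and Wilson do not.
* Eligibility: ≥ 2 admissions whose **full first-to-last span** is ≤ 1826
  days (5 × 365.25, inclusive); a consecutive-gap mode is available since
  the span reading is ambiguous in general.
* Change classification compares first vs. last **definite** labels;
  intermediate `NOT_GIVEN` admissions are ignored; patients with < 2
  definite labels are excluded with a logged reason. `DATING` ↔
  `PARTNERED` counts as a change.
* Age matching subsamples each group toward the reference group's 5-year
  age-bin profile (seeded, deterministic per group name); if the profile is
  unrealizable (tiny groups) or the stratified sample still misses the
  tolerance, members are greedily trimmed from the age-extreme end. Truly
  disjoint age ranges raise a diagnostic error.
* Mann–Whitney U uses exact enumeration when both samples have ≤ 8
  observations and no cross-sample ties, else the tie-corrected normal
  approximation. Holm adjustment is standard step-down with monotonicity
  enforcement.
* All randomness flows from a master seed through
  `sha256(master_seed, module_name)`-derived per-module seeds (< 2³¹), so
  any stage reruns reproducibly in isolation; simulated annotators draw
  from a per-(seed, index) generator so each draw is individually
  addressable.

## Problem sizes

The shipped demo uses 5,000 notes and a 2,639-patient cohort and completes
in well under five minutes on one CPU; the validation experiments use
n = 5,000 simulated votes for the precision-lift check, 3,000 + 1,000 notes
for the recall-lift check, 2,000 replicates for interval coverage, and 20
regenerated 139-patient change cohorts for parameter recovery. These sizes
put Monte-Carlo noise well inside the asserted margins while keeping the
full suite fast.

## Known limitations

* The text model is lexicon-level; no negation scope, temporality
  ("previously married"), or coreference. The template bank cannot test
  robustness to them.
* Base annotator noise is conditionally independent given the gold label;
  real extraction models share failure modes, which flatters voting
  ensembles.
* Static-group prevalence CIs are computed patient-level; published
  per-group figures in the source analysis appear to use admission-level
  denominators, so they are structurally not comparable and no attempt is
  made to match them.
* The precision-based rule's per-class reading and the abstention-handling
  choices are documented interpretations of an underspecified procedure;
  both alternatives remain available via config.
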