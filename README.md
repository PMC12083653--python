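# socialhx

Weak-supervision ensembles for extracting **marital status** from clinical
social-history notes, with downstream **longitudinal cohort outcome
statistics** — implemented end-to-end against a synthetic EHR corpus
generator, so the whole pipeline is testable without access to any
restricted clinical database.

## The problem

Marital status is a social determinant of health, but the structured
demographic field in an EHR is often missing or stale, and off-the-shelf
NLP extractors degrade on unseen note styles. A practical remedy is to
treat every imperfect source — the structured field plus two note-level
extraction models — as a *weak annotator* and aggregate their votes. Four
aggregation rules are implemented over the vote record
$(y_{\text{struct}}, y_A, y_B)$ with living-arrangement features
$(\ell_A, \ell_B)$:

1. **Unanimous vote** — commit iff $y_{\text{struct}} = y_A = y_B$, else
   abstain (`NOT_GIVEN`).
2. **Majority vote** — commit to any label held by ≥ 2 of 3 votes, else
   abstain.
3. **Precision-based** — follow the vote whose (annotator, predicted-class)
   cell has the highest precision on a disjoint tuning split; ties resolve
   by fixed annotator priority.
4. **Random forest** — a bagged tree ensemble over one-of-K encodings of
   all five categorical features, which can learn annotator-specific trust.

Voting raises precision at the cost of recall (abstentions). Recall is
recovered by **weak supervision**: the ensemble pseudo-labels an
unannotated corpus, abstentions are dropped, and a bag-of-ngrams
multinomial logistic *student* is fitted to the pseudo-labels. The student
scores raw text, so it cannot abstain.

Two harmonization rules handle the partner spectrum: a `PARTNERED` label is
kept only with cohabitation evidence (otherwise demoted to `SINGLE`), or —
in the improved variant — routed to a derived `DATING` class.

Downstream, patients with ≥ 2 ICU admissions no more than 5 years apart are
classified by comparing first vs. last definite status into *same* /
*got married* / *other change* groups, and per-condition incidence
(flag off at first admission, on later) and recovery (on at first, off at
last) are reported as exact Clopper–Pearson proportions

$$\mathrm{CI}_{95}(x, n) = \left[\,Q_{\mathrm{Beta}}(0.025;\,x,\,n-x+1),\;
Q_{\mathrm{Beta}}(0.975;\,x+1,\,n-x)\,\right],$$

with comorbidity-burden (Elixhauser–van Walraven score) contrasts via the
Mann–Whitney rank-sum test, Holm-adjusted.

## Worked example

```bash
socialhx run-all --config configs/demo.yaml --seed 2 --outdir run/
```

runs the full pipeline (5,000 synthetic notes; a 2,639-patient cohort with
2,500 stable-status patients, 40 who got married and 99 with another
change) and prints the per-stage row counts:

```
{"cohort_patients": 2639, "corpus": 5000, "label_sources": 11,
 "pool": 3500, "pool_majority_kept": 3186, "pool_majority_dropped": 314,
 "pool_unanimous_kept": 1781, "pool_unanimous_dropped": 1719, ...}
```

`run/evaluation.json` then contains one report per label source (weighted
precision / recall shown):

| source | wPrec | wRec |
|---|---|---|
| structured field | 0.846 | 0.793 |
| model A / model B | 0.879 / 0.829 | 0.848 / 0.768 |
| unanimous vote | 0.938 | 0.556 |
| majority vote | 0.954 | 0.907 |
| student (majority) | 1.000 | 1.000 |

The pattern is the method's point: unanimity buys precision but abstains on
36% of notes; the majority vote keeps most of the precision gain at far
higher recall; and the student trained on the majority's pseudo-labels
recovers the remaining recall (on this synthetic corpus the cue signal is
fully learnable, so it saturates). `run/outcomes.json` reports, for the
change cohort (n=47 eligible after the 5-year span filter), a depression
incidence of 12.8% (95% CI [4.8, 25.7]) against 6.7% [5.0, 8.6] in the
stable group, recovery 10.6% vs 4.0% — change patients both acquire and
shed diagnoses more often — and a significantly higher comorbidity burden
for divorced vs. married patients (Holm-adjusted p < 0.001).

## Layout

| module | role |
|---|---|
| `socialhx.synthgen` | synthetic note corpora + longitudinal cohorts |
| `socialhx.annotators` | pattern / structured / simulated annotators, harmonization |
| `socialhx.ensembles` | the four vote-aggregation strategies |
| `socialhx.weak_supervision` | pseudo-labeling + bag-of-ngrams student |
| `socialhx.evaluation` | multiclass metrics (macro / weighted / micro) |
| `socialhx.cohort_outcomes` | eligibility, change classes, exact CIs, rank tests |
| `socialhx.pipeline`, `socialhx.cli` | one-config orchestration, `socialhx` CLI |

See `docs/methods.md` for the statistical model, generator assumptions,
defaults and limitations.
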