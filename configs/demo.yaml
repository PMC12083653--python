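# Demo experiment: full pipeline at desk scale.
master_seed: 1

corpus:
  n_notes: 5000
  structured_missing_rate: 0.10
  structured_stale_rate: 0.10

cohort:
  change_group_sizes:
    SAME: 2500
    GOT_MARRIED: 40
    OTHER_CHANGE: 99

split:
  tune_frac: 0.15
  test_frac: 0.15

annotators:
  model_a_accuracy: 0.85
  model_b_accuracy: 0.75
  dating_category: true

strategies: [unanimous, majority, precision, forest]

student:
  l2: 1.0e-3
  max_iter: 500
  tol: 1.0e-6

forest:
  n_trees: 200
  max_depth: 8

cohort_rules:
  min_admissions: 2
  max_span_years: 5.0
  span_mode: span
  age_tolerance_years: 2.0
  reference_group: MARRIED
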