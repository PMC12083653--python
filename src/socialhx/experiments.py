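"""Self-contained validation experiments.

Each function runs one headline check of the pipeline from scratch —
simulated-annotator ensembles, weak-supervision recall recovery, exact
binomial coverage, change-cohort parameter recovery — and returns plain
numbers. They power both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from socialhx import ensembles as ens
from socialhx import weak_supervision as ws
from socialhx.annotators import ConfusionSpec, SimulatedAnnotator
from socialhx.cohort_outcomes import exact_binomial_ci, transition_rates
from socialhx.evaluation import evaluate
from socialhx.labels import ChangeClass, LivingLabel, MaritalLabel
from socialhx.synthgen import CohortSpec, CorpusSpec, TUNE_CLASS_MIX, generate_cohort, generate_corpus
from socialhx.synthgen.cohort import DEFAULT_NEW_DIAGNOSIS, DEFAULT_RECOVERY

M = MaritalLabel

#: Change-cohort size: 40 patients who got married + 99 with another change.
CHANGE_N = 139


def change_cohort_cis(level: float = 0.95) -> dict[str, dict[str, float]]:
    """Exact Clopper–Pearson intervals for the change cohort's incidence and
    recovery rates at n=139, with event counts reconstructed from the
    generator's default change-group rates as round(rate * n).

    Returns percentages rounded to one decimal.
    """
    out: dict[str, dict[str, float]] = {}
    for kind, rates in (("new", DEFAULT_NEW_DIAGNOSIS["CHANGE"]),
                        ("recovery", DEFAULT_RECOVERY["CHANGE"])):
        for cond, rate in rates.items():
            x = round(rate * CHANGE_N)
            lo, hi = exact_binomial_ci(x, CHANGE_N, level)
            out[f"{kind}_{cond}"] = {
                "x": x,
                "pct": round(100 * x / CHANGE_N, 1),
                "lo_pct": round(100 * lo, 1),
                "hi_pct": round(100 * hi, 1),
            }
    return out


def _definite_mix() -> dict[MaritalLabel, float]:
    mix = {c: p for c, p in TUNE_CLASS_MIX.items() if c is not M.NOT_GIVEN}
    total = sum(mix.values())
    return {c: p / total for c, p in mix.items()}


def _simulate_votes(golds, accuracies, seed):
    sims = [
        SimulatedAnnotator(ConfusionSpec.uniform_noise(acc, seed=seed + 17 * (k + 1)))
        for k, acc in enumerate(accuracies)
    ]
    return [
        ens.VoteRecord(
            note_id=f"n{i}",
            marital_votes=tuple(s.annotate(g, i) for s in sims),
            living_votes=(LivingLabel.NOT_GIVEN, LivingLabel.NOT_GIVEN),  # unused
        )
        for i, g in enumerate(golds)
    ]


def ensemble_precision_lift(seed: int, n: int = 5000, accuracy: float = 0.75) -> dict:
    """Majority vote over three conditionally independent annotators of equal
    accuracy (uniform errors): weighted precision on the notes where the vote
    is definite, against each base annotator's weighted precision."""
    rng = np.random.default_rng(seed)
    mix = TUNE_CLASS_MIX
    classes = list(mix)
    golds = [
        classes[i]
        for i in rng.choice(len(classes), size=n, p=np.array(list(mix.values())))
    ]
    votes = _simulate_votes(golds, (accuracy,) * 3, seed)

    base_precisions = {}
    for k, name in enumerate(ens.ANNOTATORS):
        preds = [v.marital_votes[k] for v in votes]
        base_precisions[name] = evaluate(golds, preds).aggregates.weighted_precision

    decisions = [ens.majority_decision(v) for v in votes]
    definite = [(g, d.label) for g, d in zip(golds, decisions) if not d.abstained]
    definite_gold = [g for g, _ in definite]
    definite_pred = [p for _, p in definite]
    majority_precision = evaluate(definite_gold, definite_pred).aggregates.weighted_precision
    return {
        "majority_weighted_precision_definite": majority_precision,
        "base_weighted_precisions": base_precisions,
        "n_definite": len(definite),
        "n": n,
    }


def weak_supervision_recall_lift(
    seed: int,
    n_train: int = 3000,
    n_test: int = 1000,
    annotator_accuracy: float = 0.6,
) -> dict:
    """Teacher (majority vote over three 60%-accurate annotators) abstains on
    roughly 30% of notes; the student trained on the teacher's pseudo-labels
    is compared on a held-out gold set via macro recall."""
    mix = _definite_mix()
    corpus = generate_corpus(
        CorpusSpec(n_notes=n_train + n_test, class_mix=mix, seed=seed)
    )
    train, test = corpus[:n_train], corpus[n_train:]
    golds_train = [r.gold_status for r in train]
    golds_test = [r.gold_status for r in test]

    votes_train = _simulate_votes(golds_train, (annotator_accuracy,) * 3, seed + 1)
    decisions = {
        r.note_id: ens.majority_decision(v) for r, v in zip(train, votes_train)
    }
    pool = ws.pseudo_label(train, decisions, "majority")
    student = ws.train_student(pool, seed=seed)

    votes_test = _simulate_votes(golds_test, (annotator_accuracy,) * 3, seed + 2)
    teacher_preds = [ens.majority_vote(v) for v in votes_test]
    student_preds = [student.predict(r.text) for r in test]

    teacher_macro = evaluate(golds_test, teacher_preds).aggregates.macro_recall
    student_macro = evaluate(golds_test, student_preds).aggregates.macro_recall
    return {
        "teacher_macro_recall": teacher_macro,
        "student_macro_recall": student_macro,
        "teacher_abstention_rate": pool.n_dropped / max(1, pool.n_kept + pool.n_dropped),
        "pool_kept": pool.n_kept,
        "n_test": n_test,
    }


def cp_coverage(seed: int, reps: int = 2000, p: float = 0.07, n: int = 139) -> dict:
    """Empirical coverage of the 95% Clopper–Pearson interval under repeated
    binomial sampling; exact intervals are conservative, so coverage should
    sit at or above the nominal level."""
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, p, size=reps)
    cache: dict[int, tuple[float, float]] = {}
    hits = 0
    for x in draws:
        x = int(x)
        if x not in cache:
            cache[x] = exact_binomial_ci(x, n, 0.95)
        lo, hi = cache[x]
        hits += lo <= p <= hi
    return {"coverage": hits / reps, "reps": reps, "p": p, "n": n}


def change_parameter_recovery(seed: int, reps: int = 20) -> dict:
    """Generate ``reps`` seeded change cohorts (40 got married + 99 other
    change) at the default new-diagnosis/recovery rates, re-estimate the six
    rates with the pipeline estimator, and report how often each estimate's
    Clopper–Pearson interval covers its generating value."""
    sizes = {ChangeClass.GOT_MARRIED: 40, ChangeClass.OTHER_CHANGE: 99}
    targets = {
        f"new_{cond}": rate for cond, rate in DEFAULT_NEW_DIAGNOSIS["CHANGE"].items()
    }
    targets.update(
        {f"recovery_{cond}": rate for cond, rate in DEFAULT_RECOVERY["CHANGE"].items()}
    )
    covered = {k: 0 for k in targets}
    for r in range(reps):
        cohort = generate_cohort(
            CohortSpec(change_group_sizes=sizes, seed=seed + r)
        )
        for cond in DEFAULT_NEW_DIAGNOSIS["CHANGE"]:
            new, rec = transition_rates(cohort, cond)
            if new.lower <= targets[f"new_{cond}"] <= new.upper:
                covered[f"new_{cond}"] += 1
            if rec.lower <= targets[f"recovery_{cond}"] <= rec.upper:
                covered[f"recovery_{cond}"] += 1
    per_rate = {k: v / reps for k, v in covered.items()}
    pooled = sum(covered.values()) / (reps * len(covered))
    return {"per_rate_coverage": per_rate, "pooled_coverage": pooled, "reps": reps}
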