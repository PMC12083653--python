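"""End-to-end experiment orchestration.

``run_experiment`` executes: synthetic corpus -> three weak annotators ->
four vote-aggregation ensembles -> pseudo-label / student bootstrapping ->
evaluation of all eleven label sources (3 base annotators + 4 ensembles +
4 students) -> synthetic cohort -> change-cohort outcome statistics. Every
stage is seeded from the master seed; rerunning with an identical config is
byte-identical, which the artifact manifest (config hash + SHA256 of every
output file) makes checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from socialhx import annotators as ann
from socialhx import cohort_outcomes as co
from socialhx import ensembles as ens
from socialhx import evaluation as ev
from socialhx import weak_supervision as ws
from socialhx.config import ExperimentConfig, derive_seed
from socialhx.labels import CONDITIONS, ChangeClass, MaritalLabel
from socialhx.records import NoteRecord, write_cohort, write_corpus
from socialhx.synthgen import generate_cohort, generate_corpus

logger = logging.getLogger(__name__)


def _annotate(
    records: list[NoteRecord], config: ExperimentConfig
) -> list[ens.VoteRecord]:
    """Produce aligned vote records from the three weak annotators."""
    acfg = config.annotators
    harmonize = ann.derive_dating if acfg.dating_category else ann.recode_partnered
    noise_a = ann.SimulatedAnnotator(
        ann.ConfusionSpec.uniform_noise(
            acfg.model_a_accuracy, seed=derive_seed(config.master_seed, "model_a")
        )
    )
    noise_b = ann.SimulatedAnnotator(
        ann.ConfusionSpec.uniform_noise(
            acfg.model_b_accuracy, seed=derive_seed(config.master_seed, "model_b")
        )
    )
    votes = []
    for i, rec in enumerate(records):
        structured = ann.structured_annotate(rec)
        base = ann.pattern_annotate(rec.text, rec.note_id)
        vote_a = harmonize(noise_a.annotate(base.marital, i), base.cohab)
        vote_b = harmonize(noise_b.annotate(base.marital, i), base.cohab)
        votes.append(
            ens.VoteRecord(
                note_id=rec.note_id,
                marital_votes=(structured.marital, vote_a, vote_b),
                living_votes=(base.living, base.living),
            )
        )
    return votes


def _gold(records: list[NoteRecord], config: ExperimentConfig) -> list[MaritalLabel]:
    """Evaluation gold: the generator's label, harmonized the same way the
    model votes are (stage 1 folds dating into single)."""
    if config.annotators.dating_category:
        return [r.gold_status for r in records]
    return [
        MaritalLabel.SINGLE if r.gold_status is MaritalLabel.DATING else r.gold_status
        for r in records
    ]


def _votes_df(votes: list[ens.VoteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "note_id": [v.note_id for v in votes],
            "structured": [v.marital_votes[0].value for v in votes],
            "model_a": [v.marital_votes[1].value for v in votes],
            "model_b": [v.marital_votes[2].value for v in votes],
            "living_a": [v.living_votes[0].value for v in votes],
            "living_b": [v.living_votes[1].value for v in votes],
        }
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n", encoding="utf-8")


def _cohort_outcomes(timelines, config: ExperimentConfig) -> dict:
    rules = config.cohort_rules
    eligible = co.select_eligible(
        timelines,
        co.EligibilityRule(
            min_admissions=rules.min_admissions,
            max_span_years=rules.max_span_years,
            mode=rules.span_mode,
        ),
    )
    # static groups by first definite status, age-matched to the reference
    static: dict[str, list] = {}
    for tl in eligible:
        static.setdefault(tl.statuses[0].value, []).append(tl)
    ref = rules.reference_group
    if ref in static:
        for name in sorted(static):
            if name == ref:
                continue
            try:
                matched = co.downsample_age_match(
                    {name: static[name], ref: static[ref]},
                    ref,
                    tolerance_years=rules.age_tolerance_years,
                    seed=derive_seed(config.master_seed, "age_match"),
                )
                static[name] = matched[name]
            except ValueError as exc:
                logger.warning("age matching skipped for %s: %s", name, exc)

    change_groups: dict[str, list] = {c.value: [] for c in ChangeClass}
    n_excluded = 0
    for tl in eligible:
        cls = co.classify_change(tl)
        if cls is None:
            n_excluded += 1
            continue
        change_groups[cls.value].append(tl)

    out: dict = {
        "n_eligible": len(eligible),
        "n_excluded_change": n_excluded,
        "static": {},
        "change": {},
        "evw": {},
    }
    for name, members in sorted(static.items()):
        entry = {
            "n": len(members),
            "mean_age": round(float(pd.Series([t.age_at_first for t in members]).mean()), 2),
        }
        for cond in CONDITIONS:
            ci = co.prevalence(members, cond)
            p, lo, hi = ci.as_percent()
            entry[cond] = {"x": ci.x, "pct": p, "ci": [lo, hi]}
        out["static"][name] = entry

    pooled_change = change_groups[ChangeClass.GOT_MARRIED.value] + change_groups[
        ChangeClass.OTHER_CHANGE.value
    ]
    for name, members in [
        ("SAME", change_groups[ChangeClass.SAME.value]),
        ("CHANGE", pooled_change),
        ("GOT_MARRIED", change_groups[ChangeClass.GOT_MARRIED.value]),
        ("OTHER_CHANGE", change_groups[ChangeClass.OTHER_CHANGE.value]),
    ]:
        if not members:
            continue
        entry = {"n": len(members)}
        for cond in CONDITIONS:
            new, rec = co.transition_rates(members, cond)
            np_, nlo, nhi = new.as_percent()
            rp_, rlo, rhi = rec.as_percent()
            entry[cond] = {
                "new_diagnosis": {"x": new.x, "pct": np_, "ci": [nlo, nhi]},
                "recovery": {"x": rec.x, "pct": rp_, "ci": [rlo, rhi]},
            }
        out["change"][name] = entry

    # comorbidity-burden contrasts vs the reference group, Holm-adjusted
    if ref in static:
        ref_scores = [t.evw_score for t in static[ref]]
        names = [n for n in sorted(static) if n != ref]
        raw = []
        for name in names:
            stat, p = co.rank_sum_compare([t.evw_score for t in static[name]], ref_scores)
            raw.append((name, stat, p))
        adjusted = co.holm_adjust([p for _, _, p in raw]) if raw else []
        for (name, stat, p), p_adj in zip(raw, adjusted):
            out["evw"][f"{name}_vs_{ref}"] = {
                "U": stat,
                "p": round(p, 6),
                "p_holm": round(p_adj, 6),
            }
    return out


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> dict:
    """Run every stage, write artifacts under ``outdir``, return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    corpus = generate_corpus(config.corpus_spec())
    write_corpus(corpus, outdir / "corpus.jsonl")
    counts["corpus"] = len(corpus)

    n_tune = int(len(corpus) * config.split.tune_frac)
    n_test = int(len(corpus) * config.split.test_frac)
    tune, test, pool = (
        corpus[:n_tune],
        corpus[n_tune : n_tune + n_test],
        corpus[n_tune + n_test :],
    )
    counts.update(tune=len(tune), test=len(test), pool=len(pool))

    votes = _annotate(corpus, config)
    by_id = {v.note_id: v for v in votes}
    _votes_df(votes).to_csv(outdir / "votes.csv", index=False)

    gold_all = _gold(corpus, config)
    gold_map = {r.note_id: g for r, g in zip(corpus, gold_all)}
    tune_votes = [by_id[r.note_id] for r in tune]
    tune_gold = [gold_map[r.note_id] for r in tune]
    test_votes = [by_id[r.note_id] for r in test]
    test_gold = [gold_map[r.note_id] for r in test]

    table = ens.compute_precision_table(
        {
            name: [v.marital_votes[i] for v in tune_votes]
            for i, name in enumerate(ens.ANNOTATORS)
        },
        tune_gold,
    )
    forest = ens.train_forest(
        tune_votes,
        tune_gold,
        ens.ForestConfig(
            n_trees=config.forest.n_trees,
            max_depth=config.forest.max_depth,
            seed=derive_seed(config.master_seed, "forest"),
        ),
    )

    reports: dict[str, dict] = {}
    include_zero = config.evaluation.include_zero_support
    for i, name in enumerate(ens.ANNOTATORS):
        preds = [v.marital_votes[i] for v in test_votes]
        reports[name] = ev.evaluate(test_gold, preds, include_zero_support=include_zero).to_dict()

    for strategy in config.strategies:
        decisions = {
            v.note_id: ens.decide(strategy, v, table=table, forest=forest) for v in votes
        }
        labels_df = pd.DataFrame(
            {
                "note_id": [v.note_id for v in votes],
                "label": [decisions[v.note_id].label.value for v in votes],
                "abstained": [int(decisions[v.note_id].abstained) for v in votes],
            }
        )
        labels_df.to_csv(outdir / f"labels_{strategy}.csv", index=False)

        preds = [decisions[r.note_id].label for r in test]
        reports[f"ensemble_{strategy}"] = ev.evaluate(
            test_gold, preds, include_zero_support=include_zero
        ).to_dict()

        pl = ws.pseudo_label(
            pool,
            decisions,
            strategy,
            keep_abstentions=config.student.keep_abstentions,
        )
        counts[f"pool_{strategy}_kept"] = pl.n_kept
        counts[f"pool_{strategy}_dropped"] = pl.n_dropped
        student = ws.train_student(
            pl,
            ws.StudentHyperparams(
                l2=config.student.l2,
                max_iter=config.student.max_iter,
                tol=config.student.tol,
            ),
            seed=derive_seed(config.master_seed, f"student_{strategy}"),
        )
        student.save(outdir / f"student_{strategy}.json")
        student_preds = [student.predict(r.text) for r in test]
        reports[f"student_{strategy}"] = ev.evaluate(
            test_gold, student_preds, include_zero_support=include_zero
        ).to_dict()

    _write_json(outdir / "evaluation.json", reports)
    counts["label_sources"] = len(reports)

    timelines = generate_cohort(config.cohort_spec())
    write_cohort(timelines, outdir / "cohort.csv")
    counts["cohort_patients"] = len(timelines)

    outcomes = _cohort_outcomes(timelines, config)
    _write_json(outdir / "outcomes.json", outcomes)

    artifacts = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "counts": counts,
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest
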