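"""Vote-aggregation strategies: oracle equivalence, precision table, forest."""

import itertools
from collections import Counter

import pytest

from socialhx import ensembles as ens
from socialhx.annotators import ConfusionSpec, SimulatedAnnotator
from socialhx.labels import (
    BASE_MARITAL_CLASSES,
    LivingLabel,
    MaritalLabel,
)

M = MaritalLabel
L = LivingLabel


def _vote(a, b, c, living=(L.NOT_GIVEN, L.NOT_GIVEN), note_id="n"):
    return ens.VoteRecord(note_id=note_id, marital_votes=(a, b, c), living_votes=living)


def _brute_unanimous(votes):
    labels = set(votes)
    return votes[0] if len(labels) == 1 else M.NOT_GIVEN


def _brute_majority(votes):
    for label, count in Counter(votes).items():
        if count >= 2:
            return label
    return M.NOT_GIVEN


def test_vote_rules_match_brute_force_over_all_triples():
    """Exhaustive oracle equivalence over all 8^3 = 512 vote triples, plus
    the abstention-ordering containment (unanimous abstains wherever
    majority does)."""
    n_checked = 0
    for triple in itertools.product(MaritalLabel, repeat=3):
        record = _vote(*triple)
        assert ens.unanimous_vote(record) == _brute_unanimous(triple)
        assert ens.majority_vote(record) == _brute_majority(triple)
        if ens.majority_decision(record).abstained:
            assert ens.unanimous_decision(record).abstained
        n_checked += 1
    assert n_checked == 512


def test_precision_table_hand_counts():
    gold = [M.MARRIED, M.SINGLE, M.SINGLE]
    preds = {"structured": [M.MARRIED, M.MARRIED, M.SINGLE],
             "model_a": gold, "model_b": gold}
    table = ens.compute_precision_table(preds, gold)
    assert table.get("structured", M.MARRIED) == pytest.approx(1 / 2)
    assert table.get("structured", M.SINGLE) == pytest.approx(1.0)
    assert table.get("model_a", M.MARRIED) == 1.0
    # never-predicted class: flagged undefined, stored 0
    assert ("structured", M.DIVORCED) in table.undefined
    assert table.get("structured", M.DIVORCED) == 0.0


def test_precision_table_alignment_error():
    with pytest.raises(ValueError):
        ens.compute_precision_table({"model_a": [M.MARRIED]}, [M.MARRIED, M.SINGLE])


def test_precision_select_argmax_and_tiebreak():
    table = ens.PrecisionTable(
        precision={
            ("structured", M.MARRIED): 0.9,
            ("model_a", M.SINGLE): 0.6,
            ("model_b", M.DIVORCED): 0.7,
        },
        predicted={},
    )
    assert ens.precision_select(_vote(M.MARRIED, M.SINGLE, M.DIVORCED), table) is M.MARRIED
    # unanimous votes are invariant to the table
    assert ens.precision_select(_vote(M.MARRIED, M.MARRIED, M.MARRIED), table) is M.MARRIED
    # exact tie between model_a and model_b cells -> model_a (priority order)
    tie = ens.PrecisionTable(
        precision={("model_a", M.SINGLE): 0.7, ("model_b", M.DIVORCED): 0.7},
        predicted={},
    )
    assert ens.precision_select(_vote(M.WIDOWED, M.SINGLE, M.DIVORCED), tie) is M.SINGLE


def test_precision_select_dominant_annotator_reduces_to_it():
    """If one annotator's precision dominates every class, the strategy
    reproduces that annotator's predictions exactly."""
    precision = {}
    for cls in MaritalLabel:
        precision[("model_b", cls)] = 0.9
        precision[("model_a", cls)] = 0.4
        precision[("structured", cls)] = 0.3
    table = ens.PrecisionTable(precision=precision, predicted={})
    for triple in itertools.product([M.MARRIED, M.SINGLE, M.WIDOWED], repeat=3):
        assert ens.precision_select(_vote(*triple), table) is triple[2]


def _simulated_votes(accuracies, golds, seed_base=100):
    sims = [
        SimulatedAnnotator(ConfusionSpec.uniform_noise(acc, seed=seed_base + k))
        for k, acc in enumerate(accuracies)
    ]
    votes = []
    for i, g in enumerate(golds):
        triple = tuple(s.annotate(g, i) for s in sims)
        votes.append(_vote(*triple, note_id=f"n{i}"))
    return votes


def test_forest_learns_to_trust_reliable_annotator():
    """With one 95%-accurate model among two 40% noisers, the trained forest
    beats the majority vote on held-out accuracy (the vote cannot learn
    annotator-specific trust)."""
    import numpy as np

    rng = np.random.default_rng(11)
    classes = list(BASE_MARITAL_CLASSES[:-1])  # definite classes
    golds = [classes[i] for i in rng.integers(0, len(classes), size=2000)]
    votes = _simulated_votes((0.4, 0.4, 0.95), golds, seed_base=200)
    train_v, test_v = votes[:1000], votes[1000:]
    train_g, test_g = golds[:1000], golds[1000:]
    forest = ens.train_forest(train_v, train_g, ens.ForestConfig(seed=11))
    forest_acc = sum(
        p is g for p, g in zip(forest.predict(test_v), test_g)
    ) / len(test_g)
    majority_acc = sum(
        ens.majority_vote(v) is g for v, g in zip(test_v, test_g)
    ) / len(test_g)
    assert forest_acc > majority_acc
    assert forest_acc > 0.9


def test_forest_trivial_fits_and_determinism():
    votes = [_vote(M.MARRIED, M.MARRIED, M.MARRIED, note_id=f"n{i}") for i in range(5)]
    gold = [M.MARRIED] * 5
    forest = ens.train_forest(votes, gold, ens.ForestConfig(n_trees=20, seed=0))
    # single-class training data -> always predicts that class
    assert ens.forest_predict(forest, _vote(M.SINGLE, M.DIVORCED, M.WIDOWED)) is M.MARRIED
    v = _vote(M.SINGLE, M.SINGLE, M.WIDOWED)
    assert ens.forest_predict(forest, v) is ens.forest_predict(forest, v)
    with pytest.raises(ValueError):
        ens.train_forest([], [], ens.ForestConfig())


def test_decide_dispatch_requires_fitted_state():
    v = _vote(M.MARRIED, M.MARRIED, M.SINGLE)
    assert ens.decide("majority", v).label is M.MARRIED
    with pytest.raises(ValueError):
        ens.decide("precision", v)
    with pytest.raises(ValueError):
        ens.decide("forest", v)
    with pytest.raises(ValueError):
        ens.decide("nope", v)
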