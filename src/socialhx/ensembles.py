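"""Four label-aggregation strategies over three weak annotators.

A vote record carries five categorical features: three marital votes
(structured field, model A, model B) and the two models' living-arrangement
votes. The strategies are:

* unanimous vote — the common label when all three marital votes agree,
  otherwise the NOT_GIVEN fallback;
* majority vote — any label held by at least two votes, otherwise fallback;
* precision-based — the vote whose (annotator, predicted-class) cell has the
  highest precision on a disjoint tuning split;
* random forest — a bagged tree ensemble over one-of-K encodings of all five
  features, which can learn annotator-specific trust.

NOT_GIVEN counts as an ordinary vote value: two annotators agreeing on
NOT_GIVEN is a genuine majority, distinct from the disagreement fallback.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import OneHotEncoder

from socialhx.labels import (
    LIVING_CLASSES,
    MARITAL_CLASSES,
    LivingLabel,
    MaritalLabel,
)

#: Annotator names in vote order.
ANNOTATORS: tuple[str, str, str] = ("structured", "model_a", "model_b")

#: Tie-break priority for the precision-based strategy (best individual
#: text models first, structured field last).
PRECISION_TIE_PRIORITY: tuple[str, str, str] = ("model_a", "model_b", "structured")


@dataclass
class VoteRecord:
    """Aligned votes for one note: 3 marital + 2 living labels."""

    note_id: str
    marital_votes: tuple[MaritalLabel, MaritalLabel, MaritalLabel]
    living_votes: tuple[LivingLabel, LivingLabel]

    def __post_init__(self) -> None:
        if len(self.marital_votes) != 3 or len(self.living_votes) != 2:
            raise ValueError("a vote record needs exactly 3 marital and 2 living votes")


@dataclass
class EnsembleDecision:
    """A strategy's label plus whether it is an abstention fallback."""

    label: MaritalLabel
    abstained: bool = False


# --------------------------------------------------------------------------
# voting rules
# --------------------------------------------------------------------------


def unanimous_decision(votes: VoteRecord) -> EnsembleDecision:
    a, b, c = votes.marital_votes
    if a == b == c:
        return EnsembleDecision(a, abstained=False)
    return EnsembleDecision(MaritalLabel.NOT_GIVEN, abstained=True)


def unanimous_vote(votes: VoteRecord) -> MaritalLabel:
    """Common label of all three marital votes, else the NOT_GIVEN fallback."""
    return unanimous_decision(votes).label


def majority_decision(votes: VoteRecord) -> EnsembleDecision:
    counts = Counter(votes.marital_votes)
    label, n = counts.most_common(1)[0]
    if n >= 2:
        return EnsembleDecision(label, abstained=False)
    return EnsembleDecision(MaritalLabel.NOT_GIVEN, abstained=True)


def majority_vote(votes: VoteRecord) -> MaritalLabel:
    """Label held by >= 2 of 3 marital votes; three-way splits fall back."""
    return majority_decision(votes).label


# --------------------------------------------------------------------------
# precision-based strategy
# --------------------------------------------------------------------------


@dataclass
class PrecisionTable:
    """Per-(annotator, class) precision estimated on a tuning split.

    Cells with zero predictions of a class are undefined; they are stored as
    0.0 and flagged, and participate in the argmax as 0 (a prediction that
    was never validated is never trusted).
    """

    precision: dict[tuple[str, MaritalLabel], float]
    predicted: dict[tuple[str, MaritalLabel], int]
    undefined: set = field(default_factory=set)

    def get(self, annotator: str, label: MaritalLabel) -> float:
        return self.precision.get((annotator, label), 0.0)


def compute_precision_table(
    predictions: Mapping[str, Sequence[MaritalLabel]],
    gold: Sequence[MaritalLabel],
) -> PrecisionTable:
    """Precision of every annotator for every class it predicts."""
    if not gold:
        raise ValueError("empty tuning split")
    precision: dict[tuple[str, MaritalLabel], float] = {}
    predicted: dict[tuple[str, MaritalLabel], int] = {}
    undefined = set()
    for name, preds in predictions.items():
        if len(preds) != len(gold):
            raise ValueError(f"predictions of {name!r} not aligned with gold")
        for cls in MARITAL_CLASSES:
            total = sum(1 for p in preds if p == cls)
            correct = sum(1 for p, g in zip(preds, gold) if p == cls and g == cls)
            predicted[(name, cls)] = total
            if total == 0:
                precision[(name, cls)] = 0.0
                undefined.add((name, cls))
            else:
                precision[(name, cls)] = correct / total
    return PrecisionTable(precision=precision, predicted=predicted, undefined=undefined)


def precision_select(
    votes: VoteRecord,
    table: PrecisionTable,
    priority: Sequence[str] = PRECISION_TIE_PRIORITY,
) -> MaritalLabel:
    """Return the vote whose (annotator, label) cell has the highest tuning
    precision; exact ties resolve by the fixed annotator priority order."""
    by_name = dict(zip(ANNOTATORS, votes.marital_votes))
    best_label, best_score = MaritalLabel.NOT_GIVEN, -1.0
    for name in priority:
        label = by_name[name]
        score = table.get(name, label)
        if score > best_score:
            best_label, best_score = label, score
    return best_label


def precision_select_global(votes: VoteRecord, table: PrecisionTable) -> MaritalLabel:
    """Alternative reading: always follow the single annotator with the best
    prediction-weighted mean precision on the tuning split."""
    def overall(name: str) -> float:
        num = sum(
            table.precision[(name, c)] * table.predicted[(name, c)]
            for c in MARITAL_CLASSES
        )
        den = sum(table.predicted[(name, c)] for c in MARITAL_CLASSES)
        return num / den if den else 0.0

    best = max(PRECISION_TIE_PRIORITY, key=lambda n: (overall(n), -PRECISION_TIE_PRIORITY.index(n)))
    return dict(zip(ANNOTATORS, votes.marital_votes))[best]


# --------------------------------------------------------------------------
# random-forest strategy
# --------------------------------------------------------------------------


@dataclass
class ForestConfig:
    n_trees: int = 200
    max_depth: int = 8
    seed: int = 0


class ForestModel:
    """Random forest over one-of-K encodings of the 5 categorical votes."""

    def __init__(self, config: ForestConfig):
        self.config = config
        marital_vocab = [c.value for c in MARITAL_CLASSES]
        living_vocab = [c.value for c in LIVING_CLASSES]
        self._encoder = OneHotEncoder(
            categories=[marital_vocab] * 3 + [living_vocab] * 2,
            handle_unknown="ignore",
        )
        self._forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_features="sqrt",
            random_state=config.seed,
        )

    @staticmethod
    def _rows(records: Sequence[VoteRecord]) -> list[list[str]]:
        return [
            [v.value for v in r.marital_votes] + [v.value for v in r.living_votes]
            for r in records
        ]

    def fit(self, records: Sequence[VoteRecord], gold: Sequence[MaritalLabel]) -> "ForestModel":
        if not records:
            raise ValueError("empty training set")
        if len(records) != len(gold):
            raise ValueError("vote records not aligned with gold labels")
        X = self._encoder.fit_transform(self._rows(records))
        self._forest.fit(X, [g.value for g in gold])
        return self

    def predict(self, records: Sequence[VoteRecord]) -> list[MaritalLabel]:
        X = self._encoder.transform(self._rows(records))
        return [MaritalLabel(v) for v in self._forest.predict(X)]


def train_forest(
    records: Sequence[VoteRecord],
    gold: Sequence[MaritalLabel],
    config: ForestConfig | None = None,
) -> ForestModel:
    """Fit the forest meta-classifier; deterministic given ``config.seed``."""
    return ForestModel(config or ForestConfig()).fit(records, gold)


def forest_predict(model: ForestModel, votes: VoteRecord) -> MaritalLabel:
    """Plurality over trees; deterministic after training."""
    return model.predict([votes])[0]


# --------------------------------------------------------------------------
# strategy dispatch
# --------------------------------------------------------------------------

STRATEGIES: tuple[str, ...] = ("unanimous", "majority", "precision", "forest")


def decide(
    strategy: str,
    votes: VoteRecord,
    table: PrecisionTable | None = None,
    forest: ForestModel | None = None,
) -> EnsembleDecision:
    """Apply one strategy to one vote record.

    Only the unanimous and majority rules can abstain; the precision-based
    and forest strategies always commit to a label.
    """
    if strategy == "unanimous":
        return unanimous_decision(votes)
    if strategy == "majority":
        return majority_decision(votes)
    if strategy == "precision":
        if table is None:
            raise ValueError("precision strategy needs a PrecisionTable")
        return EnsembleDecision(precision_select(votes, table), abstained=False)
    if strategy == "forest":
        if forest is None:
            raise ValueError("forest strategy needs a trained ForestModel")
        return EnsembleDecision(forest_predict(forest, votes), abstained=False)
    raise ValueError(f"unknown strategy {strategy!r}")
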