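"""Multiclass evaluation with macro / weighted / micro averaging.

Per-class precision, recall and F1 are aggregated two ways: the macro
average is the unweighted mean over classes with nonzero gold support (empty
classes would otherwise drag the mean down; a config flag restores the
include-everything behavior), and the weighted average weights each class by
its gold support. Weighted recall then coincides with micro accuracy — an
algebraic identity the test suite fuzzes. NOT_GIVEN is scored as an ordinary
class: annotated sets genuinely contain "no status given" notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from socialhx.labels import MARITAL_CLASSES, MaritalLabel


@dataclass
class ConfusionMatrix:
    """Gold rows x predicted columns."""

    classes: tuple
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    precision_defined: bool = True
    recall_defined: bool = True


@dataclass
class Aggregates:
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float


@dataclass
class EvaluationReport:
    per_class: dict
    aggregates: Aggregates
    classes: tuple
    flagged: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(getattr(c, "value", c)): vars(m) for c, m in self.per_class.items()
            },
            "aggregates": vars(self.aggregates),
            "flagged": [str(f) for f in self.flagged],
        }


def confusion(
    gold: Sequence, pred: Sequence, classes: Sequence | None = None
) -> ConfusionMatrix:
    """Count co-occurrences of (gold, predicted) labels."""
    if len(gold) != len(pred):
        raise ValueError("gold and predictions are not aligned")
    if classes is None:
        classes = MARITAL_CLASSES
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for g, p in zip(gold, pred):
        counts[index[g], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def per_class_metrics(cm: ConfusionMatrix) -> dict:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
    zero denominators yield 0 with the corresponding flag cleared."""
    out = {}
    for i, cls in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fp = int(cm.counts[:, i].sum()) - tp
        fn = int(cm.counts[i, :].sum()) - tp
        p_def, r_def = (tp + fp) > 0, (tp + fn) > 0
        precision = tp / (tp + fp) if p_def else 0.0
        recall = tp / (tp + fn) if r_def else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        out[cls] = ClassMetrics(
            precision=precision,
            recall=recall,
            f1=f1,
            support=tp + fn,
            precision_defined=p_def,
            recall_defined=r_def,
        )
    return out


def aggregate(
    per_class: dict,
    include_zero_support: bool = False,
    accuracy: float | None = None,
) -> Aggregates:
    """Macro (unweighted over supported classes), weighted (support-weighted)
    and micro (accuracy) summaries.

    ``accuracy`` should be the confusion-matrix trace over the total (as
    :func:`evaluate` supplies); when absent it is reconstructed from per-class
    recalls, which is the same quantity up to floating-point accumulation.
    """
    items = list(per_class.items())
    macro_items = [m for _, m in items if include_zero_support or m.support > 0]
    if not macro_items:
        raise ValueError("no classes to aggregate")
    total = sum(m.support for _, m in items)
    if total == 0:
        raise ValueError("zero total support")

    def macro(attr: str) -> float:
        return float(np.mean([getattr(m, attr) for m in macro_items]))

    def weighted(attr: str) -> float:
        return sum(getattr(m, attr) * m.support for _, m in items) / total

    if accuracy is None:
        accuracy = sum(m.recall * m.support for _, m in items) / total
    return Aggregates(
        macro_precision=macro("precision"),
        macro_recall=macro("recall"),
        macro_f1=macro("f1"),
        weighted_precision=weighted("precision"),
        weighted_recall=weighted("recall"),
        weighted_f1=weighted("f1"),
        accuracy=accuracy,
    )


def evaluate(
    gold: Sequence,
    pred: Sequence,
    classes: Sequence | None = None,
    include_zero_support: bool = False,
) -> EvaluationReport:
    """End-to-end: confusion -> per-class metrics -> aggregates."""
    cm = confusion(gold, pred, classes)
    per_class = per_class_metrics(cm)
    flagged = [
        c for c, m in per_class.items() if not (m.precision_defined and m.recall_defined)
    ]
    accuracy = float(np.trace(cm.counts)) / cm.total if cm.total else 0.0
    return EvaluationReport(
        per_class=per_class,
        aggregates=aggregate(per_class, include_zero_support, accuracy=accuracy),
        classes=cm.classes,
        flagged=flagged,
    )
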