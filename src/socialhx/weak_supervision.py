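"""Pseudo-label bootstrapping of a text student classifier.

An ensemble (the teacher) labels an unannotated corpus; notes on which the
teacher abstained are dropped; and a bag-of-ngrams multinomial logistic
classifier (the student) is fitted to the remaining pseudo-labels. Because
the student scores raw text it cannot abstain, so it recovers recall on the
notes the teacher could not decide. The module exposes a plain
text -> label interface, so heavier encoders can be slotted in behind it.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from sklearn.linear_model import LogisticRegression

from socialhx.labels import MARITAL_CLASSES, MaritalLabel
from socialhx.records import NoteRecord

logger = logging.getLogger(__name__)

_TOKEN = re.compile(r"[a-z0-9]+")

#: Canonical index of each marital class, used to order student classes.
_CLASS_ORDER = {c: i for i, c in enumerate(MARITAL_CLASSES)}


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric unigrams plus adjacent bigrams."""
    unigrams = _TOKEN.findall(text.lower())
    bigrams = [f"{a} {b}" for a, b in zip(unigrams, unigrams[1:])]
    return unigrams + bigrams


@dataclass
class PseudoLabel:
    note_id: str
    text: str
    pseudo_label: MaritalLabel
    source_ensemble: str


@dataclass
class PseudoLabeledPool:
    records: list[PseudoLabel]
    n_kept: int
    n_dropped: int
    source_ensemble: str


def pseudo_label(
    corpus: Sequence[NoteRecord],
    decisions: Mapping[str, "EnsembleDecisionLike"],
    strategy: str,
    keep_abstentions: bool = False,
) -> PseudoLabeledPool:
    """Build the training pool from teacher decisions.

    Abstention fallbacks (the NOT_GIVEN the unanimous/majority rules emit on
    disagreement) are "no decision", not "no information in the note", and
    are excluded by default. A genuinely predicted NOT_GIVEN — e.g. all
    voters agreeing the note gives no status — is kept as a class.
    """
    kept: list[PseudoLabel] = []
    dropped = 0
    for rec in corpus:
        decision = decisions[rec.note_id]
        if decision.abstained and not keep_abstentions:
            dropped += 1
            continue
        kept.append(PseudoLabel(rec.note_id, rec.text, decision.label, strategy))
    logger.info(
        "pseudo_label[%s]: kept %d, dropped %d abstentions", strategy, len(kept), dropped
    )
    return PseudoLabeledPool(kept, n_kept=len(kept), n_dropped=dropped, source_ensemble=strategy)


class EnsembleDecisionLike:
    """Protocol-ish: anything with ``.label`` and ``.abstained``."""

    label: MaritalLabel
    abstained: bool


@dataclass
class StudentHyperparams:
    l2: float = 1e-3
    max_iter: int = 500
    tol: float = 1e-6


@dataclass
class StudentModel:
    """Bag-of-ngrams multinomial logistic classifier.

    ``weights`` has one row per class (in ``classes`` order, itself sorted by
    the canonical marital class order) and one column per vocabulary term.
    Serialization to JSON round-trips exactly (floats stored with full repr).
    """

    vocabulary: dict[str, int]
    classes: list[MaritalLabel]
    weights: np.ndarray  # (n_classes, n_features)
    bias: np.ndarray  # (n_classes,)
    hyperparams: StudentHyperparams = field(default_factory=StudentHyperparams)
    seed: int = 0

    def featurize(self, text: str) -> csr_matrix:
        return featurize_text(text, self.vocabulary)

    def decision_scores(self, text: str) -> np.ndarray:
        x = self.featurize(text)
        return np.asarray(x @ self.weights.T).ravel() + self.bias

    def predict(self, text: str) -> MaritalLabel:
        scores = self.decision_scores(text)
        return self.classes[int(np.argmax(scores))]

    def to_json(self) -> str:
        return json.dumps(
            {
                "vocabulary": self.vocabulary,
                "classes": [c.value for c in self.classes],
                "weights": self.weights.tolist(),
                "bias": self.bias.tolist(),
                "hyperparams": vars(self.hyperparams),
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "StudentModel":
        d = json.loads(payload)
        return cls(
            vocabulary={k: int(v) for k, v in d["vocabulary"].items()},
            classes=[MaritalLabel(c) for c in d["classes"]],
            weights=np.array(d["weights"], dtype=float),
            bias=np.array(d["bias"], dtype=float),
            hyperparams=StudentHyperparams(**d["hyperparams"]),
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "StudentModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def featurize_text(text: str, vocabulary: dict[str, int]) -> csr_matrix:
    """Sparse term-frequency vector over a fixed vocabulary.

    Out-of-vocabulary tokens are ignored; the L1 norm of the vector equals
    the number of kept token and bigram occurrences.
    """
    counts: dict[int, float] = {}
    for term in tokenize(text):
        idx = vocabulary.get(term)
        if idx is not None:
            counts[idx] = counts.get(idx, 0.0) + 1.0
    if not counts:
        return csr_matrix((1, len(vocabulary)))
    cols = sorted(counts)
    data = [counts[c] for c in cols]
    return csr_matrix((data, ([0] * len(cols), cols)), shape=(1, len(vocabulary)))


def _build_vocabulary(texts: Sequence[str]) -> dict[str, int]:
    terms = sorted({t for text in texts for t in tokenize(text)})
    return {t: i for i, t in enumerate(terms)}


def _design_matrix(texts: Sequence[str], vocabulary: dict[str, int]) -> csr_matrix:
    rows, cols, data = [], [], []
    for i, text in enumerate(texts):
        counts: dict[int, float] = {}
        for term in tokenize(text):
            idx = vocabulary.get(term)
            if idx is not None:
                counts[idx] = counts.get(idx, 0.0) + 1.0
        for c, v in counts.items():
            rows.append(i)
            cols.append(c)
            data.append(v)
    return csr_matrix((data, (rows, cols)), shape=(len(texts), len(vocabulary)))


def train_student(
    pool: PseudoLabeledPool,
    hyperparams: StudentHyperparams | None = None,
    seed: int = 0,
) -> StudentModel:
    """Fit the student on a pseudo-labeled pool.

    The objective is the per-sample-averaged multinomial log-loss plus an L2
    penalty, minimized by a deterministic full-batch quasi-Newton solver to
    the configured tolerance. Averaging the loss makes the fit invariant to
    duplicating the pool. A single-class pool degenerates to a constant
    predictor (with a warning).
    """
    hp = hyperparams or StudentHyperparams()
    if not pool.records:
        raise ValueError("empty pseudo-labeled pool")
    texts = [r.text for r in pool.records]
    labels = [r.pseudo_label for r in pool.records]
    vocab = _build_vocabulary(texts)
    classes = sorted(set(labels), key=_CLASS_ORDER.__getitem__)

    if len(classes) == 1:
        warnings.warn(
            f"single-class pool ({classes[0].value}); returning constant predictor",
            stacklevel=2,
        )
        weights = np.zeros((1, len(vocab)))
        bias = np.zeros(1)
        return StudentModel(vocab, classes, weights, bias, hp, seed)

    X = _design_matrix(texts, vocab)
    y = np.array([classes.index(lab) for lab in labels])
    # C = 1/(l2 * n): sklearn's objective becomes mean log-loss + l2 * ||w||^2 / 2
    clf = LogisticRegression(
        C=1.0 / (hp.l2 * len(texts)),
        solver="lbfgs",
        max_iter=hp.max_iter,
        tol=hp.tol,
        random_state=seed,
    )
    clf.fit(X, y)
    weights = np.zeros((len(classes), len(vocab)))
    bias = np.zeros(len(classes))
    if len(classes) == 2:
        # sklearn stores one row for the positive class in the binary case
        weights[1] = clf.coef_[0]
        bias[1] = clf.intercept_[0]
    else:
        for row, cls_idx in enumerate(clf.classes_):
            weights[int(cls_idx)] = clf.coef_[row]
            bias[int(cls_idx)] = clf.intercept_[row]
    return StudentModel(vocab, classes, weights, bias, hp, seed)


def student_predict(model: StudentModel, text: str) -> MaritalLabel:
    """Argmax class score; ties break by canonical class order. Never abstains
    unless NOT_GIVEN was among the trained classes."""
    return model.predict(text)
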