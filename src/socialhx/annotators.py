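"""Weak base annotators and label-harmonization rules.

Three kinds of label sources feed the ensembles:

* :func:`structured_annotate` — the structured demographic field, mapped
  through an editable raw-token vocabulary; it carries no living information.
* :func:`pattern_annotate` — a deterministic cue-lexicon extractor standing
  in for off-the-shelf note-level models; ordered rules, first match wins,
  with rarer statuses (widowed, divorced, separated) taking precedence over
  marriage and partner cues so that e.g. "separated from spouse" is not
  shadowed by a spouse cue.
* :class:`SimulatedAnnotator` — a confusion-matrix-driven labeler for
  controlled parameter-recovery experiments.

Two harmonization rules post-process model output: partnered labels are kept
only with cohabitation evidence (:func:`recode_partnered`, which demotes the
rest to single), or routed to the derived DATING class
(:func:`derive_dating`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from socialhx.labels import (
    BASE_MARITAL_CLASSES,
    Cohabitation,
    ConfigurationError,
    LivingLabel,
    MaritalLabel,
)
from socialhx.records import NoteRecord

M = MaritalLabel
L = LivingLabel


@dataclass
class AnnotatorOutput:
    """Per-note labels from one annotator."""

    note_id: str
    marital: MaritalLabel
    living: LivingLabel
    cohab: Cohabitation


# --------------------------------------------------------------------------
# pattern annotator
# --------------------------------------------------------------------------

#: Ordered marital rule list; first match wins.
MARITAL_RULES: tuple[tuple[MaritalLabel, re.Pattern], ...] = (
    (M.WIDOWED, re.compile(r"\b(widowed|widower|widow)\b", re.I)),
    (M.DIVORCED, re.compile(r"\b(divorced|divorce)\b", re.I)),
    (M.SEPARATED, re.compile(r"\b(separated|separation)\b", re.I)),
    (M.MARRIED, re.compile(r"\b(married|wife|husband|spouse)\b", re.I)),
    (M.PARTNERED, re.compile(r"\b(partner|girlfriend|boyfriend)\b", re.I)),
    (M.SINGLE, re.compile(r"\b(single)\b", re.I)),
)

_LIVING_RULES: tuple[tuple[LivingLabel, re.Pattern], ...] = (
    (L.ALONE, re.compile(r"\b(?:lives?|living)\s+alone\b|\blives?\s+by\s+(?:him|her)self\b", re.I)),
    (
        L.WITH_FAMILY,
        re.compile(
            r"\b(?:lives?|living|home)\s+(?:at\s+home\s+)?with\s+(?:\w+\s+)?"
            r"(wife|husband|spouse|partner|girlfriend|boyfriend|family|daughter|son|"
            r"mother|father|parents|children|kids)\b",
            re.I,
        ),
    ),
    (
        L.WITH_OTHERS,
        re.compile(
            r"\b(?:lives?|living|resides?)\s+(?:in\s+a\s+group\s+home\s+)?with\s+"
            r"(?:a\s+)?(roommates?|friends?|others)\b|\bgroup\s+home\b",
            re.I,
        ),
    ),
)

_PARTNER_TERM = r"(?:wife|husband|spouse|partner|girlfriend|boyfriend)"
_COHAB_WITH = re.compile(
    r"\b(?:lives?|living)\s+(?:at\s+home\s+)?with\s+(?:\w+\s+)?" + _PARTNER_TERM + r"\b",
    re.I,
)
_COHAB_NEG = re.compile(
    r"\b(?:does\s+not|doesn't|not)\s+(?:live|living)\s+with\b", re.I
)
_ALONE = re.compile(
    r"\b(?:lives?|living)\s+alone\b|\blives?\s+by\s+(?:him|her)self\b", re.I
)


def _detect_cohabitation(text: str) -> Cohabitation:
    """Sentence-level cohabitation cue detection.

    An explicit "lives with <partner term>" in a non-negated sentence wins;
    otherwise "lives alone" (or a negated live-with) marks non-cohabitation.
    """
    verdict = Cohabitation.UNKNOWN
    for sentence in re.split(r"[.;\n]", text):
        if _COHAB_WITH.search(sentence) and not _COHAB_NEG.search(sentence):
            return Cohabitation.WITH_PARTNER
        if _ALONE.search(sentence) or (
            _COHAB_NEG.search(sentence) and re.search(_PARTNER_TERM, sentence, re.I)
        ):
            verdict = Cohabitation.NOT_WITH_PARTNER
    return verdict


def pattern_annotate(text: str, note_id: str = "") -> AnnotatorOutput:
    """Apply the ordered cue lexicons to one note. Total and deterministic."""
    marital = M.NOT_GIVEN
    for label, pattern in MARITAL_RULES:
        if pattern.search(text):
            marital = label
            break
    living = L.NOT_GIVEN
    for label, pattern in _LIVING_RULES:
        if pattern.search(text):
            living = label
            break
    return AnnotatorOutput(note_id, marital, living, _detect_cohabitation(text))


# --------------------------------------------------------------------------
# structured-field annotator
# --------------------------------------------------------------------------

#: Default raw-token vocabulary of the structured marital-status field.
DEFAULT_STRUCTURED_MAPPING: dict[str, MaritalLabel] = {
    "MARRIED": M.MARRIED,
    "SINGLE": M.SINGLE,
    "WIDOWED": M.WIDOWED,
    "DIVORCED": M.DIVORCED,
    "SEPARATED": M.SEPARATED,
    "LIFE PARTNER": M.PARTNERED,
    "UNKNOWN (DEFAULT)": M.NOT_GIVEN,
    "": M.NOT_GIVEN,
}


def structured_annotate(
    record: NoteRecord, mapping: Mapping[str, MaritalLabel] | None = None
) -> AnnotatorOutput:
    """Map the raw structured token to a marital label.

    The structured field carries no living-arrangement information, so the
    living label is always NOT_GIVEN and cohabitation UNKNOWN.
    """
    mapping = DEFAULT_STRUCTURED_MAPPING if mapping is None else mapping
    token = record.structured_status.strip().upper()
    marital = mapping.get(token, M.NOT_GIVEN)
    return AnnotatorOutput(record.note_id, marital, L.NOT_GIVEN, Cohabitation.UNKNOWN)


# --------------------------------------------------------------------------
# simulated annotators
# --------------------------------------------------------------------------


@dataclass
class ConfusionSpec:
    """Per-true-class emission rows over the base marital vocabulary."""

    rows: dict[MaritalLabel, dict[MaritalLabel, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        self.rows = {
            MaritalLabel(g): {MaritalLabel(p): float(v) for p, v in row.items()}
            for g, row in self.rows.items()
        }
        for gold, row in self.rows.items():
            if any(v < 0 or v > 1 for v in row.values()):
                raise ConfigurationError(f"row {gold} has out-of-range probabilities")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"row {gold} does not sum to 1")

    @classmethod
    def uniform_noise(
        cls,
        accuracy: float,
        classes: Sequence[MaritalLabel] = BASE_MARITAL_CLASSES,
        seed: int = 0,
    ) -> "ConfusionSpec":
        """Correct with probability ``accuracy``; errors uniform over the rest."""
        k = len(classes)
        rows = {}
        for gold in classes:
            err = (1.0 - accuracy) / (k - 1)
            rows[gold] = {c: (accuracy if c is gold else err) for c in classes}
        return cls(rows=rows, seed=seed)


class SimulatedAnnotator:
    """Confusion-matrix labeler, deterministic given (seed, draw index)."""

    def __init__(self, conf: ConfusionSpec):
        self.conf = conf

    def annotate(self, gold: MaritalLabel, draw_index: int) -> MaritalLabel:
        row = self.conf.rows.get(MaritalLabel(gold))
        if row is None:
            raise ConfigurationError(f"no confusion row for gold class {gold}")
        rng = np.random.default_rng([self.conf.seed, draw_index])
        labels = list(row)
        p = np.array([row[lab] for lab in labels], dtype=float)
        return labels[int(rng.choice(len(labels), p=p / p.sum()))]

    def annotate_many(self, golds: Iterable[MaritalLabel]) -> list[MaritalLabel]:
        return [self.annotate(g, i) for i, g in enumerate(golds)]


def simulate_annotator(
    gold: MaritalLabel, conf: ConfusionSpec, draw_index: int = 0
) -> MaritalLabel:
    """Single draw from ``conf``'s row for ``gold``."""
    return SimulatedAnnotator(conf).annotate(gold, draw_index)


# --------------------------------------------------------------------------
# harmonization rules
# --------------------------------------------------------------------------


def recode_partnered(marital: MaritalLabel, cohab: Cohabitation) -> MaritalLabel:
    """Keep PARTNERED only with cohabitation evidence; demote the rest to SINGLE.

    This is the first-stage harmonization, under which dating (non-cohabiting)
    individuals are treated as single. All other labels pass through.
    """
    if marital is M.PARTNERED and cohab is not Cohabitation.WITH_PARTNER:
        return M.SINGLE
    return marital


def derive_dating(marital: MaritalLabel, cohab: Cohabitation) -> MaritalLabel:
    """Route non-cohabiting PARTNERED labels to the derived DATING class."""
    if marital is M.PARTNERED and cohab is not Cohabitation.WITH_PARTNER:
        return M.DATING
    return marital
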