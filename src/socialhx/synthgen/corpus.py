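"""Synthetic note-corpus generator.

Each note is a short social-history section assembled from a marital cue
sentence, an optional living-arrangement sentence, and cue-free filler. The
structured demographic field mirrors the gold status through a raw-token
vocabulary, but can be missing (empty token) or stale (the token of a
uniformly chosen *other* status), emulating outdated registration data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from socialhx.labels import (
    BASE_MARITAL_CLASSES,
    ConfigurationError,
    LivingLabel,
    MaritalLabel,
)
from socialhx.records import NoteRecord
from socialhx.synthgen import templates as T

#: Default marital class mix: the manually annotated tuning-split composition
#: (53 single, 49 partnered, 117 married, 6 separated, 34 divorced,
#: 42 widowed, 21 not given; the singleton engaged note is excluded).
TUNE_CLASS_MIX: dict[MaritalLabel, float] = {
    MaritalLabel.SINGLE: 53 / 322,
    MaritalLabel.PARTNERED: 49 / 322,
    MaritalLabel.MARRIED: 117 / 322,
    MaritalLabel.SEPARATED: 6 / 322,
    MaritalLabel.DIVORCED: 34 / 322,
    MaritalLabel.WIDOWED: 42 / 322,
    MaritalLabel.NOT_GIVEN: 21 / 322,
}

DEFAULT_LIVING_MIX: dict[LivingLabel, float] = {
    LivingLabel.ALONE: 0.30,
    LivingLabel.WITH_FAMILY: 0.45,
    LivingLabel.WITH_OTHERS: 0.10,
    LivingLabel.NOT_GIVEN: 0.15,
}

_MIX_TOL = 1e-9


def _check_mix(mix: dict, name: str) -> None:
    if not mix:
        raise ConfigurationError(f"{name} is empty")
    for k, v in mix.items():
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{name}[{k}] = {v} outside [0, 1]")
    total = float(sum(mix.values()))
    if abs(total - 1.0) > _MIX_TOL:
        raise ConfigurationError(f"{name} sums to {total!r}, expected 1")


@dataclass
class CorpusSpec:
    """Configuration for :func:`generate_corpus`.

    ``cue_noise_rate`` is the probability that a note's marital cue sentence
    is replaced by filler, which removes the lexical signal for that note and
    lets tests degrade the pattern annotator gradually.
    """

    n_notes: int
    class_mix: dict[MaritalLabel, float] = field(
        default_factory=lambda: dict(TUNE_CLASS_MIX)
    )
    living_mix: dict[LivingLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_LIVING_MIX)
    )
    structured_missing_rate: float = 0.10
    structured_stale_rate: float = 0.10
    cue_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 0:
            raise ConfigurationError("n_notes must be >= 0")
        self.class_mix = {MaritalLabel(k): float(v) for k, v in self.class_mix.items()}
        self.living_mix = {LivingLabel(k): float(v) for k, v in self.living_mix.items()}
        _check_mix(self.class_mix, "class_mix")
        _check_mix(self.living_mix, "living_mix")
        for r in ("structured_missing_rate", "structured_stale_rate", "cue_noise_rate"):
            v = getattr(self, r)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{r} = {v} outside [0, 1]")
        if self.structured_missing_rate + self.structured_stale_rate > 1.0 + _MIX_TOL:
            raise ConfigurationError("missing + stale rates exceed 1")


def _choice(rng: np.random.Generator, items, probs=None):
    idx = rng.choice(len(items), p=probs)
    return items[int(idx)]


def _structured_token(
    rng: np.random.Generator, gold: MaritalLabel, spec: CorpusSpec
) -> str:
    u = rng.random()
    if u < spec.structured_missing_rate:
        return ""
    if u < spec.structured_missing_rate + spec.structured_stale_rate:
        others = [c for c in BASE_MARITAL_CLASSES
                  if c is not gold and c is not MaritalLabel.NOT_GIVEN]
        return T.STRUCTURED_TOKEN[_choice(rng, others)]
    return T.STRUCTURED_TOKEN[gold]


def _render_note(
    rng: np.random.Generator, gold: MaritalLabel, living: LivingLabel, spec: CorpusSpec
) -> tuple[str, LivingLabel]:
    sentences: list[str] = []

    marital_sentence = ""
    if T.MARITAL_TEMPLATES[gold]:
        marital_sentence = _choice(rng, T.MARITAL_TEMPLATES[gold])
    # cue dropout: the note loses its lexical marital signal
    if marital_sentence and rng.random() < spec.cue_noise_rate:
        marital_sentence = ""
    if marital_sentence:
        sentences.append(marital_sentence)

    if gold is MaritalLabel.PARTNERED:
        # cohabiting by definition: the partner cohabitation sentence doubles
        # as the living-arrangement sentence
        living = LivingLabel.WITH_FAMILY
        sentences.append(_choice(rng, T.PARTNER_COHAB_TEMPLATES))
    elif gold is MaritalLabel.MARRIED and living is LivingLabel.WITH_FAMILY:
        if rng.random() < 0.5:
            sentences.append(_choice(rng, T.SPOUSE_COHAB_TEMPLATES))
        else:
            sentences.append(_choice(rng, T.LIVING_TEMPLATES[living]))
    elif T.LIVING_TEMPLATES[living]:
        sentences.append(_choice(rng, T.LIVING_TEMPLATES[living]))

    n_filler = 1 + int(rng.integers(0, 2))
    for _ in range(n_filler):
        sentences.append(_choice(rng, T.FILLER_TEMPLATES))

    return " ".join(sentences), living


def generate_corpus(spec: CorpusSpec) -> list[NoteRecord]:
    """Generate ``spec.n_notes`` note records, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_mix)
    class_p = np.array([spec.class_mix[c] for c in classes], dtype=float)
    class_p = class_p / class_p.sum()
    livings = list(spec.living_mix)
    living_p = np.array([spec.living_mix[c] for c in livings], dtype=float)
    living_p = living_p / living_p.sum()

    records: list[NoteRecord] = []
    for i in range(spec.n_notes):
        gold = _choice(rng, classes, class_p)
        living = _choice(rng, livings, living_p)
        if gold is MaritalLabel.DATING and living is LivingLabel.NOT_GIVEN:
            # a dating note needs non-cohabitation evidence to be resolvable
            living = LivingLabel.ALONE
        text, living = _render_note(rng, gold, living, spec)
        records.append(
            NoteRecord(
                note_id=f"note-{i:06d}",
                patient_id=f"pt-{i:06d}",
                admission_id=f"adm-{i:06d}",
                text=text,
                structured_status=_structured_token(rng, gold, spec),
                gold_status=gold,
                gold_living=living,
            )
        )
    return records
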