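"""Closed label vocabularies shared across the pipeline.

Marital status uses an eight-class vocabulary. ENGAGED is deliberately not a
class: engaged patients are too rare to score and are folded into the partner
spectrum upstream. DATING is a *derived* class — base annotators never emit
it; it is produced only by :func:`socialhx.annotators.derive_dating` from a
PARTNERED label whose cohabitation evidence is absent.
"""

from __future__ import annotations

from enum import Enum


class ConfigurationError(ValueError):
    """Raised for invalid generator/annotator configuration (bad mixes, rows)."""


class MaritalLabel(str, Enum):
    MARRIED = "MARRIED"
    SINGLE = "SINGLE"
    PARTNERED = "PARTNERED"
    DATING = "DATING"
    SEPARATED = "SEPARATED"
    DIVORCED = "DIVORCED"
    WIDOWED = "WIDOWED"
    NOT_GIVEN = "NOT_GIVEN"


class LivingLabel(str, Enum):
    ALONE = "ALONE"
    WITH_FAMILY = "WITH_FAMILY"
    WITH_OTHERS = "WITH_OTHERS"
    NOT_GIVEN = "NOT_GIVEN"


class Cohabitation(str, Enum):
    WITH_PARTNER = "WITH_PARTNER"
    NOT_WITH_PARTNER = "NOT_WITH_PARTNER"
    UNKNOWN = "UNKNOWN"


class ChangeClass(str, Enum):
    SAME = "SAME"
    GOT_MARRIED = "GOT_MARRIED"
    OTHER_CHANGE = "OTHER_CHANGE"


#: Canonical class order used for deterministic tie-breaking everywhere.
MARITAL_CLASSES: tuple[MaritalLabel, ...] = tuple(MaritalLabel)

#: Labels base annotators may emit (everything except the derived DATING class).
BASE_MARITAL_CLASSES: tuple[MaritalLabel, ...] = tuple(
    c for c in MaritalLabel if c is not MaritalLabel.DATING
)

#: Definite (non-abstaining) marital classes.
DEFINITE_MARITAL_CLASSES: tuple[MaritalLabel, ...] = tuple(
    c for c in MaritalLabel if c is not MaritalLabel.NOT_GIVEN
)

LIVING_CLASSES: tuple[LivingLabel, ...] = tuple(LivingLabel)

#: Conditions tracked per admission in cohort tables.
CONDITIONS: tuple[str, ...] = ("depression", "alcohol_abuse", "drug_abuse")
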