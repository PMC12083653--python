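"""Template bank for synthetic social-history snippets.

Templates are cue-faithful by construction: a sentence written for marital
class ``s`` contains cue words from ``s``'s lexicon only, never from another
class's. This is what makes the pattern annotator's accuracy ceiling a
testable property. Filler sentences emulate the tobacco/alcohol boilerplate
of real social-history sections and are cue-free.
"""

from __future__ import annotations

from socialhx.labels import LivingLabel, MaritalLabel

M = MaritalLabel
L = LivingLabel

#: Marital-status sentences. NOT_GIVEN has no sentence (no marital cue at all).
MARITAL_TEMPLATES: dict[MaritalLabel, tuple[str, ...]] = {
    M.MARRIED: (
        "Pt is married.",
        "Patient has been married for many years.",
        "Married, supportive spouse involved in care.",
    ),
    M.SINGLE: (
        "Pt is single.",
        "Patient reports being single.",
        "Single, no long-term relationship reported.",
    ),
    M.PARTNERED: (
        "Pt has a long-term partner.",
        "Patient has a girlfriend.",
        "Patient has a boyfriend.",
    ),
    M.DATING: (
        "Pt has a girlfriend.",
        "Pt has a boyfriend.",
        "Patient reports a partner of a few months.",
    ),
    M.SEPARATED: (
        "Pt is separated.",
        "Patient is currently separated.",
        "Reports a recent marital separation.",
    ),
    M.DIVORCED: (
        "Pt is divorced.",
        "Patient divorced several years ago.",
        "Divorced, no current relationship.",
    ),
    M.WIDOWED: (
        "Pt is widowed.",
        "Patient is a widow.",
        "Patient is a widower.",
        "Widowed many years ago.",
    ),
    M.NOT_GIVEN: (),
}

#: Living-arrangement sentences that carry no marital or partner cue.
LIVING_TEMPLATES: dict[LivingLabel, tuple[str, ...]] = {
    L.ALONE: (
        "Lives alone.",
        "Lives alone in an apartment.",
        "Currently living alone.",
    ),
    L.WITH_FAMILY: (
        "Lives with family.",
        "Lives at home with her daughter.",
        "Lives with his parents.",
    ),
    L.WITH_OTHERS: (
        "Lives with a roommate.",
        "Lives with friends.",
        "Resides in a group home with others.",
    ),
    L.NOT_GIVEN: (),
}

#: Cohabitation sentences for married patients (spouse terms are MARRIED cues).
SPOUSE_COHAB_TEMPLATES: tuple[str, ...] = (
    "Lives with wife.",
    "Lives with husband.",
    "Lives at home with spouse.",
)

#: Cohabitation sentences for cohabiting partnered patients.
PARTNER_COHAB_TEMPLATES: tuple[str, ...] = (
    "Lives with partner.",
    "Lives with girlfriend.",
    "Lives with boyfriend.",
)

#: Cue-free filler emulating substance-use boilerplate.
FILLER_TEMPLATES: tuple[str, ...] = (
    "Tobacco: quit ten years ago.",
    "Denies alcohol use.",
    "Former smoker with a 20 pack-year history.",
    "No illicit drug use.",
    "Drinks socially on weekends.",
    "Retired schoolteacher.",
    "Works as an accountant.",
    "Denies tobacco use.",
    "Remote history of smoking.",
)

#: Structured-field token recorded for each gold status. The demographic
#: field has no dating concept and files dating patients under SINGLE.
STRUCTURED_TOKEN: dict[MaritalLabel, str] = {
    M.MARRIED: "MARRIED",
    M.SINGLE: "SINGLE",
    M.PARTNERED: "LIFE PARTNER",
    M.DATING: "SINGLE",
    M.SEPARATED: "SEPARATED",
    M.DIVORCED: "DIVORCED",
    M.WIDOWED: "WIDOWED",
    M.NOT_GIVEN: "",
}
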