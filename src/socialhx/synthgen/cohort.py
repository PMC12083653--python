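"""Synthetic longitudinal ICU cohort generator.

Patients carry an ordered admission list (ISO dates, marital status at each
admission, per-admission diagnosis flags), an age centred near 57 years, and
an integer Elixhauser–van Walraven (E-VW) comorbidity score. Condition-flag
dynamics are parameterized directly by per-group new-diagnosis and recovery
probabilities so the downstream incidence estimators can be validated
against known generating values.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from socialhx.labels import CONDITIONS, ChangeClass, ConfigurationError, MaritalLabel
from socialhx.records import Admission, PatientTimeline

M = MaritalLabel

#: Downsampled static group sizes used as the default status distribution.
STATIC_GROUP_SIZES: dict[MaritalLabel, int] = {
    M.SINGLE: 262,
    M.DATING: 159,
    M.PARTNERED: 486,
    M.MARRIED: 3774,
    M.WIDOWED: 62,
    M.DIVORCED: 592,
}

#: Default change-cohort composition (same / got married / other change).
CHANGE_GROUP_SIZES: dict[ChangeClass, int] = {
    ChangeClass.SAME: 2500,
    ChangeClass.GOT_MARRIED: 40,
    ChangeClass.OTHER_CHANGE: 99,
}

_TOTAL_STATIC = sum(STATIC_GROUP_SIZES.values())

DEFAULT_INITIAL_STATUS: dict[MaritalLabel, float] = {
    s: n / _TOTAL_STATIC for s, n in STATIC_GROUP_SIZES.items()
}

#: Between-admission status transition rows (high persistence; rare moves).
DEFAULT_TRANSITIONS: dict[MaritalLabel, dict[MaritalLabel, float]] = {
    M.SINGLE: {M.SINGLE: 0.96, M.DATING: 0.015, M.PARTNERED: 0.01, M.MARRIED: 0.015},
    M.DATING: {M.DATING: 0.96, M.SINGLE: 0.01, M.PARTNERED: 0.02, M.MARRIED: 0.01},
    M.PARTNERED: {M.PARTNERED: 0.96, M.SINGLE: 0.01, M.DATING: 0.01, M.MARRIED: 0.02},
    M.MARRIED: {M.MARRIED: 0.96, M.DIVORCED: 0.025, M.WIDOWED: 0.015},
    M.WIDOWED: {M.WIDOWED: 0.96, M.MARRIED: 0.02, M.PARTNERED: 0.01, M.DATING: 0.01},
    M.DIVORCED: {M.DIVORCED: 0.96, M.MARRIED: 0.02, M.PARTNERED: 0.01, M.DATING: 0.01},
}

#: First-admission condition prevalence per marital status. Cells that have a
#: published point estimate use it; the remaining cells are declared package
#: defaults (see docs/methods.md).
DEFAULT_PREVALENCE: dict[MaritalLabel, dict[str, float]] = {
    M.MARRIED: {"depression": 0.0932, "alcohol_abuse": 0.0655, "drug_abuse": 0.0255},
    M.DATING: {"depression": 0.193, "alcohol_abuse": 0.183, "drug_abuse": 0.10},
    M.PARTNERED: {"depression": 0.15, "alcohol_abuse": 0.218, "drug_abuse": 0.165},
    M.WIDOWED: {"depression": 0.124, "alcohol_abuse": 0.0236, "drug_abuse": 0.0196},
    M.SINGLE: {"depression": 0.14, "alcohol_abuse": 0.12, "drug_abuse": 0.08},
    M.DIVORCED: {"depression": 0.15, "alcohol_abuse": 0.15, "drug_abuse": 0.08},
}

#: Per change-group new-diagnosis probability (flag off at first admission,
#: on at a later one) and recovery probability (on at first, off at last).
DEFAULT_NEW_DIAGNOSIS: dict[str, dict[str, float]] = {
    "CHANGE": {"depression": 0.072, "alcohol_abuse": 0.043, "drug_abuse": 0.072},
    "SAME": {"depression": 0.062, "alcohol_abuse": 0.014, "drug_abuse": 0.016},
}
DEFAULT_RECOVERY: dict[str, dict[str, float]] = {
    "CHANGE": {"depression": 0.108, "alcohol_abuse": 0.050, "drug_abuse": 0.058},
    "SAME": {"depression": 0.042, "alcohol_abuse": 0.018, "drug_abuse": 0.016},
}

#: Poisson mean of the E-VW score per first-admission status (divorced burden
#: sits above married, matching the reported median contrast 7 vs 5).
DEFAULT_EVW_MEAN: dict[MaritalLabel, float] = {
    M.MARRIED: 5.0,
    M.DIVORCED: 7.0,
    M.SINGLE: 6.0,
    M.DATING: 6.0,
    M.PARTNERED: 6.0,
    M.WIDOWED: 6.0,
}

_TOL = 1e-9


@dataclass
class CohortSpec:
    """Configuration for :func:`generate_cohort`.

    If ``change_group_sizes`` is given, generation is stratified: status
    paths are constructed to realize exactly those SAME / GOT_MARRIED /
    OTHER_CHANGE counts (every patient then has >= 2 admissions). Otherwise
    statuses follow ``status_transition_matrix`` freely.
    """

    n_patients: int = 0
    mean_age: float = 57.0
    sd_age: float = 12.0
    min_admissions: int = 1
    extra_admissions_mean: float = 1.3
    min_gap_years: float = 0.5
    max_gap_years: float = 6.0
    initial_status_probs: dict[MaritalLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_STATUS)
    )
    status_transition_matrix: dict[MaritalLabel, dict[MaritalLabel, float]] = field(
        default_factory=lambda: {s: dict(r) for s, r in DEFAULT_TRANSITIONS.items()}
    )
    prevalence: dict[MaritalLabel, dict[str, float]] = field(
        default_factory=lambda: {s: dict(r) for s, r in DEFAULT_PREVALENCE.items()}
    )
    new_diagnosis_prob: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_NEW_DIAGNOSIS.items()}
    )
    recovery_prob: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_RECOVERY.items()}
    )
    evw_mean: dict[MaritalLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_EVW_MEAN)
    )
    change_group_sizes: dict[ChangeClass, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.mean_age <= 0:
            raise ConfigurationError("mean_age must be > 0")
        self.initial_status_probs = {
            MaritalLabel(k): float(v) for k, v in self.initial_status_probs.items()
        }
        if abs(sum(self.initial_status_probs.values()) - 1.0) > 1e-6:
            raise ConfigurationError("initial_status_probs must sum to 1")
        self.status_transition_matrix = {
            MaritalLabel(s): {MaritalLabel(t): float(p) for t, p in row.items()}
            for s, row in self.status_transition_matrix.items()
        }
        for s, row in self.status_transition_matrix.items():
            if any(p < -_TOL or p > 1 + _TOL for p in row.values()):
                raise ConfigurationError(f"transition row {s} has out-of-range entries")
            if abs(sum(row.values()) - 1.0) > _TOL:
                raise ConfigurationError(f"transition row {s} does not sum to 1")
        if self.change_group_sizes is not None:
            self.change_group_sizes = {
                ChangeClass(k): int(v) for k, v in self.change_group_sizes.items()
            }


def _draw_from(rng: np.random.Generator, probs: dict[MaritalLabel, float]) -> MaritalLabel:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def _status_path_free(
    rng: np.random.Generator, spec: CohortSpec, n_adm: int
) -> list[MaritalLabel]:
    s = _draw_from(rng, spec.initial_status_probs)
    path = [s]
    for _ in range(n_adm - 1):
        row = spec.status_transition_matrix.get(s)
        if row is None:
            raise ConfigurationError(f"no transition row for status {s}")
        s = _draw_from(rng, row)
        path.append(s)
    return path


def _status_path_stratified(
    rng: np.random.Generator, spec: CohortSpec, n_adm: int, group: ChangeClass
) -> list[MaritalLabel]:
    init = dict(spec.initial_status_probs)
    if group is ChangeClass.SAME:
        s = _draw_from(rng, init)
        return [s] * n_adm
    if group is ChangeClass.GOT_MARRIED:
        init.pop(M.MARRIED, None)
        first = _draw_from(rng, init)
        last = M.MARRIED
    else:  # OTHER_CHANGE: ends on a different, non-married status
        first = _draw_from(rng, init)
        targets = {s: p for s, p in init.items() if s not in (first, M.MARRIED)}
        last = _draw_from(rng, targets)
    k = 1 + int(rng.integers(0, n_adm - 1))  # change point in [1, n_adm-1]
    return [first] * k + [last] * (n_adm - k)


def _change_group(path: list[MaritalLabel]) -> ChangeClass:
    if len(path) < 2 or path[0] == path[-1]:
        return ChangeClass.SAME
    if path[-1] is M.MARRIED:
        return ChangeClass.GOT_MARRIED
    return ChangeClass.OTHER_CHANGE


def _condition_flags(
    rng: np.random.Generator,
    spec: CohortSpec,
    cond: str,
    first_status: MaritalLabel,
    group: ChangeClass,
    n_adm: int,
) -> list[bool]:
    prev = spec.prevalence.get(first_status, {}).get(cond, 0.0)
    gkey = "SAME" if group is ChangeClass.SAME else "CHANGE"
    pn = spec.new_diagnosis_prob.get(gkey, {}).get(cond, 0.0) if n_adm >= 2 else 0.0
    pr = spec.recovery_prob.get(gkey, {}).get(cond, 0.0) if n_adm >= 2 else 0.0
    u = rng.random()
    if u < pn:  # incident diagnosis: off at first, turns on later, stays on
        onset = 1 + int(rng.integers(0, n_adm - 1))
        return [i >= onset for i in range(n_adm)]
    if u < pn + pr:  # recovery: on at first, off by the last admission
        off = 1 + int(rng.integers(0, n_adm - 1))
        return [i < off for i in range(n_adm)]
    # constant flag; baseline chosen so the first-admission marginal matches
    # the per-status prevalence: prev = pr + (1 - pn - pr) * q
    denom = 1.0 - pn - pr
    q = (prev - pr) / denom if denom > 0 else 0.0
    q = float(np.clip(q, 0.0, 1.0))
    return [rng.random() < q] * n_adm


def _dates(rng: np.random.Generator, spec: CohortSpec, n_adm: int) -> list[datetime.date]:
    start = datetime.date(2000, 1, 1) + datetime.timedelta(
        days=int(rng.integers(0, 3653))
    )
    dates = [start]
    for _ in range(n_adm - 1):
        gap_days = max(1, int(round(rng.uniform(spec.min_gap_years, spec.max_gap_years) * 365.25)))
        dates.append(dates[-1] + datetime.timedelta(days=gap_days))
    return dates


def generate_cohort(spec: CohortSpec) -> list[PatientTimeline]:
    """Generate patient timelines, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    if spec.change_group_sizes is not None:
        plan: list[ChangeClass | None] = []
        for group in (ChangeClass.SAME, ChangeClass.GOT_MARRIED, ChangeClass.OTHER_CHANGE):
            plan.extend([group] * spec.change_group_sizes.get(group, 0))
    else:
        plan = [None] * spec.n_patients

    timelines: list[PatientTimeline] = []
    for i, planned in enumerate(plan):
        if planned is None:
            n_adm = max(1, spec.min_admissions + int(rng.poisson(spec.extra_admissions_mean)))
            path = _status_path_free(rng, spec, n_adm)
        else:
            n_adm = max(2, spec.min_admissions, 2 + int(rng.poisson(spec.extra_admissions_mean)))
            path = _status_path_stratified(rng, spec, n_adm, planned)
        group = _change_group(path)
        flags = {
            cond: _condition_flags(rng, spec, cond, path[0], group, n_adm)
            for cond in CONDITIONS
        }
        dates = _dates(rng, spec, n_adm)
        admissions = [
            Admission(
                date=dates[j],
                status=path[j],
                flags={cond: flags[cond][j] for cond in CONDITIONS},
            )
            for j in range(n_adm)
        ]
        age = float(np.clip(rng.normal(spec.mean_age, spec.sd_age), 18.0, 95.0))
        evw = int(rng.poisson(spec.evw_mean.get(path[0], 6.0)))
        timelines.append(
            PatientTimeline(
                patient_id=f"pt-{i:06d}",
                age_at_first=age,
                admissions=admissions,
                evw_score=evw,
            )
        )
    return timelines
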