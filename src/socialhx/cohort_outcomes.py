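"""Cohort construction and outcome statistics.

Static cohorts bin eligible patients by marital status; change cohorts
compare patients whose status changed between their first and last definite
admission labels against patients whose status stayed the same. Incidence
(new diagnosis), recovery and prevalence are reported as exact
Clopper–Pearson binomial proportions; comorbidity-burden contrasts use the
Mann–Whitney rank-sum test with step-down Holm adjustment across
comparisons.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from socialhx.labels import ChangeClass, MaritalLabel
from socialhx.records import PatientTimeline

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# eligibility and change classification
# --------------------------------------------------------------------------


@dataclass
class EligibilityRule:
    """At least ``min_admissions`` admissions within ``max_span_years``.

    ``mode`` selects whether the span constraint applies to the full
    first-to-last window ("span", default) or to every consecutive gap
    ("consecutive"). Years are converted to days (5 years = 1826 days,
    inclusive).
    """

    min_admissions: int = 2
    max_span_years: float = 5.0
    mode: str = "span"

    def __post_init__(self) -> None:
        if self.min_admissions < 2:
            raise ValueError("min_admissions must be >= 2")
        if self.max_span_years <= 0:
            raise ValueError("max_span_years must be > 0")
        if self.mode not in ("span", "consecutive"):
            raise ValueError(f"unknown eligibility mode {self.mode!r}")

    @property
    def max_span_days(self) -> int:
        return int(round(self.max_span_years * 365.25))


def select_eligible(
    timelines: Sequence[PatientTimeline], rule: EligibilityRule | None = None
) -> list[PatientTimeline]:
    """Keep patients satisfying the admission-count and span constraints."""
    rule = rule or EligibilityRule()
    out = []
    for tl in timelines:
        if len(tl.admissions) < rule.min_admissions:
            continue
        dates = [a.date for a in tl.admissions]
        if rule.mode == "span":
            ok = (dates[-1] - dates[0]).days <= rule.max_span_days
        else:
            ok = all(
                (b - a).days <= rule.max_span_days for a, b in zip(dates, dates[1:])
            )
        if ok:
            out.append(tl)
    return out


def classify_change(timeline: PatientTimeline) -> ChangeClass | None:
    """Compare the first and last definite (non-NOT_GIVEN) admission labels.

    Returns None (excluded, with a logged reason) when fewer than two
    definite labels exist. Intermediate NOT_GIVEN admissions are ignored, so
    the classification is invariant to them.
    """
    definite = [s for s in timeline.statuses if s is not MaritalLabel.NOT_GIVEN]
    if len(definite) < 2:
        logger.info(
            "patient %s excluded from change classification: %d definite label(s)",
            timeline.patient_id,
            len(definite),
        )
        return None
    first, last = definite[0], definite[-1]
    if first == last:
        return ChangeClass.SAME
    if last is MaritalLabel.MARRIED:
        return ChangeClass.GOT_MARRIED
    return ChangeClass.OTHER_CHANGE


# --------------------------------------------------------------------------
# age matching
# --------------------------------------------------------------------------


def _group_rng(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def downsample_age_match(
    groups: dict[str, list[PatientTimeline]],
    reference_group: str,
    tolerance_years: float = 1.0,
    seed: int = 0,
    bin_years: int = 5,
) -> dict[str, list[PatientTimeline]]:
    """Subsample groups toward the reference group's age-bin distribution
    until every group's mean age is within ``tolerance_years`` of the
    reference mean. Groups already within tolerance are returned unchanged.

    When a group is too small to realize the reference bin profile (or the
    stratified sample still misses the tolerance), members are greedily
    trimmed — always the one whose removal moves the group mean closest to
    the reference — until the tolerance is met. Disjoint age ranges, where
    even trimming to a single member cannot reach the tolerance, raise a
    diagnostic error.
    """
    if tolerance_years <= 0:
        raise ValueError("tolerance_years must be > 0")
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
    ref = groups[reference_group]
    ref_mean = float(np.mean([t.age_at_first for t in ref]))
    ref_bins = np.array([int(t.age_at_first // bin_years) for t in ref])
    bins, counts = np.unique(ref_bins, return_counts=True)
    ref_prop = {int(b): c / len(ref) for b, c in zip(bins, counts)}

    out: dict[str, list[PatientTimeline]] = {}
    for name, members in groups.items():
        mean = float(np.mean([t.age_at_first for t in members]))
        if name == reference_group or abs(mean - ref_mean) <= tolerance_years:
            out[name] = list(members)
            continue
        by_bin: dict[int, list[PatientTimeline]] = {}
        for t in members:
            by_bin.setdefault(int(t.age_at_first // bin_years), []).append(t)
        # largest size m for which the reference bin profile is realizable
        m = min(
            int(len(by_bin.get(b, [])) / p) for b, p in ref_prop.items() if p > 0
        )
        if m >= 1:
            rng = _group_rng(seed, name)
            sampled: list[PatientTimeline] = []
            for b, p in sorted(ref_prop.items()):
                want = min(int(round(m * p)), len(by_bin.get(b, [])))
                pool = sorted(by_bin.get(b, []), key=lambda t: t.patient_id)
                idx = rng.choice(len(pool), size=want, replace=False)
                sampled.extend(pool[i] for i in sorted(idx))
        else:
            sampled = sorted(members, key=lambda t: t.patient_id)
        sampled = _trim_to_mean(sampled, ref_mean, tolerance_years)
        if sampled is None:
            raise ValueError(
                f"cannot age-match group {name!r} to {reference_group!r}: "
                f"group ages do not reach the reference mean {ref_mean:.1f} "
                f"(group mean {mean:.1f}, tolerance {tolerance_years})"
            )
        out[name] = sampled
    return out


def _trim_to_mean(
    members: list[PatientTimeline], target: float, tolerance: float
) -> list[PatientTimeline] | None:
    """Greedily drop the age-extreme member that moves the mean toward the
    target; None when even a single remaining member cannot satisfy it."""
    current = sorted(members, key=lambda t: t.age_at_first)
    while current:
        mean = float(np.mean([t.age_at_first for t in current]))
        if abs(mean - target) <= tolerance:
            return current
        current.pop(-1 if mean > target else 0)
    return None


# --------------------------------------------------------------------------
# exact binomial proportions
# --------------------------------------------------------------------------


@dataclass
class ProportionCI:
    """Event count, denominator, point estimate and exact CI bounds."""

    x: int
    n: int
    p_hat: float
    level: float
    lower: float
    upper: float

    def as_percent(self, digits: int = 1) -> tuple[float, float, float]:
        from decimal import ROUND_HALF_UP, Decimal

        def r(v: float) -> float:
            return float(
                Decimal(100 * v).quantize(Decimal(f"1e-{digits}"), ROUND_HALF_UP)
            )

        return r(self.p_hat), r(self.lower), r(self.upper)


def exact_binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson bounds from Beta quantiles.

    lower = Q_Beta(alpha/2; x, n-x+1) with lower = 0 at x = 0;
    upper = Q_Beta(1-alpha/2; x+1, n-x) with upper = 1 at x = n.
    """
    if n < 1 or x < 0 or x > n:
        raise ValueError(f"invalid counts x={x}, n={n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level {level} outside (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def proportion_ci(x: int, n: int, level: float = 0.95) -> ProportionCI:
    lower, upper = exact_binomial_ci(x, n, level)
    return ProportionCI(x=x, n=n, p_hat=x / n, level=level, lower=lower, upper=upper)


def prevalence(group: Sequence[PatientTimeline], condition: str, level: float = 0.95) -> ProportionCI:
    """Proportion of patients whose condition flag is set at first admission."""
    if not group:
        raise ValueError("empty group")
    x = sum(1 for t in group if t.admissions[0].flags.get(condition, False))
    return proportion_ci(x, len(group), level)


def transition_rates(
    group: Sequence[PatientTimeline], condition: str, level: float = 0.95
) -> tuple[ProportionCI, ProportionCI]:
    """(new-diagnosis, recovery) proportions over the whole group.

    New diagnosis: flag absent at first admission, present at any later one.
    Recovery: flag present at first admission, absent at the last. The two
    event sets are disjoint for a single condition.
    """
    if not group:
        raise ValueError("empty group")
    for t in group:
        if len(t.admissions) < 2:
            raise ValueError(f"patient {t.patient_id} has fewer than 2 admissions")
    n = len(group)
    new = sum(
        1
        for t in group
        if not t.admissions[0].flags.get(condition, False)
        and any(a.flags.get(condition, False) for a in t.admissions[1:])
    )
    rec = sum(
        1
        for t in group
        if t.admissions[0].flags.get(condition, False)
        and not t.admissions[-1].flags.get(condition, False)
    )
    return proportion_ci(new, n, level), proportion_ci(rec, n, level)


# --------------------------------------------------------------------------
# rank comparison and multiplicity
# --------------------------------------------------------------------------


def rank_sum_compare(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Exact enumeration when both samples have at most 8 observations and no
    cross-sample ties; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a, b = list(scores_a), list(scores_b)
    if not a or not b:
        raise ValueError("both samples must be nonempty")
    values = a + b
    no_ties = len(set(values)) == len(values)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, returned in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(p, method="holm")[1]]
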