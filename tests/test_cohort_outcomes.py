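"""Eligibility, change classification, exact binomial CIs, rank tests."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socialhx import cohort_outcomes as co
from socialhx.labels import ChangeClass, MaritalLabel
from socialhx.records import Admission, PatientTimeline

M = MaritalLabel


def _timeline(years, statuses=None, flags=None, pid="p0", age=57.0, evw=5):
    statuses = statuses or [M.MARRIED] * len(years)
    flags = flags or [{} for _ in years]
    admissions = [
        Admission(datetime.date(y, 6, 1), s, dict(f))
        for y, s, f in zip(years, statuses, flags)
    ]
    return PatientTimeline(pid, age, admissions, evw)


class TestEligibility:
    def test_span_rule(self):
        rule = co.EligibilityRule()
        assert rule.max_span_days == 1826
        close = _timeline([2001, 2003])
        far = _timeline([2001, 2007])
        single = _timeline([2001])
        assert co.select_eligible([close, far, single], rule) == [close]

    def test_consecutive_mode_rescues_long_span(self):
        tl = _timeline([2001, 2004, 2007])  # full span 6y, each gap 3y
        assert co.select_eligible([tl], co.EligibilityRule(mode="span")) == []
        assert co.select_eligible([tl], co.EligibilityRule(mode="consecutive")) == [tl]

    def test_invalid_rule(self):
        with pytest.raises(ValueError):
            co.EligibilityRule(min_admissions=1)


class TestClassifyChange:
    @pytest.mark.parametrize(
        "statuses,expected",
        [
            ([M.MARRIED, M.MARRIED], ChangeClass.SAME),
            ([M.SINGLE, M.MARRIED], ChangeClass.GOT_MARRIED),
            ([M.MARRIED, M.DIVORCED], ChangeClass.OTHER_CHANGE),
            ([M.DATING, M.PARTNERED], ChangeClass.OTHER_CHANGE),
        ],
    )
    def test_first_vs_last_definite(self, statuses, expected):
        tl = _timeline(range(2001, 2001 + len(statuses)), statuses)
        assert co.classify_change(tl) is expected

    def test_invariant_to_interleaved_not_given(self):
        a = _timeline([2001, 2002, 2003], [M.SINGLE, M.NOT_GIVEN, M.MARRIED])
        b = _timeline([2001, 2003], [M.SINGLE, M.MARRIED])
        assert co.classify_change(a) is co.classify_change(b) is ChangeClass.GOT_MARRIED

    def test_fewer_than_two_definite_labels_excluded(self):
        tl = _timeline([2001, 2002], [M.NOT_GIVEN, M.MARRIED])
        assert co.classify_change(tl) is None


class TestAgeMatch:
    @staticmethod
    def _group(rng, n, mean, pid_prefix):
        return [
            _timeline([2001, 2002], pid=f"{pid_prefix}{i}",
                      age=float(rng.normal(mean, 8)))
            for i in range(n)
        ]

    def test_groups_within_tolerance_unchanged(self):
        rng = np.random.default_rng(0)
        groups = {"a": self._group(rng, 80, 57, "a"), "b": self._group(rng, 80, 57.3, "b")}
        out = co.downsample_age_match(groups, "a", tolerance_years=2.0, seed=1)
        assert out == groups

    def test_downsampling_moves_mean_into_tolerance(self):
        rng = np.random.default_rng(3)
        groups = {"young": self._group(rng, 400, 50, "y"),
                  "ref": self._group(rng, 200, 60, "r")}
        out = co.downsample_age_match(groups, "ref", tolerance_years=1.0, seed=3)
        ref_mean = np.mean([t.age_at_first for t in out["ref"]])
        young_mean = np.mean([t.age_at_first for t in out["young"]])
        assert abs(young_mean - ref_mean) <= 1.0
        assert len(out["young"]) < 400
        # deterministic given the seed
        again = co.downsample_age_match(groups, "ref", tolerance_years=1.0, seed=3)
        assert [t.patient_id for t in again["young"]] == [t.patient_id for t in out["young"]]

    def test_disjoint_ranges_error_and_empty_group_error(self):
        rng = np.random.default_rng(4)
        groups = {"kids": self._group(rng, 30, 20, "k"),
                  "ref": self._group(rng, 30, 80, "r")}
        with pytest.raises(ValueError):
            co.downsample_age_match(groups, "ref", tolerance_years=1.0, seed=0)
        with pytest.raises(ValueError):
            co.downsample_age_match({"a": [], "ref": groups["ref"]}, "ref")


class TestExactBinomial:
    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (10, 139, (0.035, 0.128)),
            (6, 139, (0.016, 0.092)),
            (15, 139, (0.062, 0.172)),
        ],
    )
    def test_change_cohort_bounds_to_three_decimals(self, x, n, expected):
        lo, hi = co.exact_binomial_ci(x, n, 0.95)
        assert round(lo, 3) == expected[0]
        assert round(hi, 3) == expected[1]

    def test_boundary_counts(self):
        lo, hi = co.exact_binomial_ci(0, 50)
        assert lo == 0.0 and hi < 1.0
        lo, hi = co.exact_binomial_ci(50, 50)
        assert lo > 0.0 and hi == 1.0

    def test_domain_errors(self):
        for bad in [(5, 0), (-1, 10), (11, 10)]:
            with pytest.raises(ValueError):
                co.exact_binomial_ci(*bad)
        with pytest.raises(ValueError):
            co.exact_binomial_ci(1, 10, level=1.5)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(1, 60))
    def test_bounds_monotone_in_x_and_contain_p_hat(self, n):
        prev_lo, prev_hi = -1.0, -1.0
        for x in range(n + 1):
            lo, hi = co.exact_binomial_ci(x, n)
            assert lo <= x / n <= hi
            assert lo >= prev_lo and hi >= prev_hi
            prev_lo, prev_hi = lo, hi


class TestRates:
    def test_prevalence_trivial_extremes(self):
        on = [_timeline([2001, 2002], flags=[{"depression": True}] * 2, pid=f"p{i}")
              for i in range(5)]
        ci = co.prevalence(on, "depression")
        assert ci.p_hat == 1.0 and ci.upper == 1.0
        off = [_timeline([2001, 2002], flags=[{"depression": False}] * 2, pid=f"q{i}")
               for i in range(5)]
        ci = co.prevalence(off, "depression")
        assert ci.p_hat == 0.0 and ci.lower == 0.0

    def test_transition_rates_hand_toy(self):
        """5 patients: 2 new diagnoses, 1 recovery -> (2/5, 1/5); the event
        sets are disjoint by construction."""
        group = [
            _timeline([2001, 2002], flags=[{"depression": False}, {"depression": True}], pid="p1"),
            _timeline([2001, 2002], flags=[{"depression": False}, {"depression": True}], pid="p2"),
            _timeline([2001, 2002], flags=[{"depression": True}, {"depression": False}], pid="p3"),
            _timeline([2001, 2002], flags=[{"depression": False}, {"depression": False}], pid="p4"),
            _timeline([2001, 2002], flags=[{"depression": True}, {"depression": True}], pid="p5"),
        ]
        new, rec = co.transition_rates(group, "depression")
        assert (new.x, new.n) == (2, 5)
        assert (rec.x, rec.n) == (1, 5)

    def test_constant_flags_give_zero_rates(self):
        group = [_timeline([2001, 2002], flags=[{"depression": True}] * 2, pid=f"p{i}")
                 for i in range(4)]
        new, rec = co.transition_rates(group, "depression")
        assert new.x == 0 and rec.x == 0

    def test_single_admission_patient_rejected(self):
        with pytest.raises(ValueError):
            co.transition_rates([_timeline([2001])], "depression")


class TestRankAndHolm:
    def test_exact_small_sample_enumeration(self):
        stat, p = co.rank_sum_compare([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_null_center(self):
        stat, p = co.rank_sum_compare([1, 2, 3, 4] * 5, [1, 2, 3, 4] * 5)
        assert p > 0.9

    def test_shift_alternative_power(self):
        """n=200 per arm with a 2-unit shift: p < 0.001 in >= 95% of reps."""
        rng = np.random.default_rng(8)
        hits = 0
        reps = 40
        for _ in range(reps):
            a = rng.normal(0, 1, 200)
            b = rng.normal(2, 1, 200)
            _, p = co.rank_sum_compare(a, b)
            hits += p < 0.001
        assert hits / reps >= 0.95

    @pytest.mark.parametrize(
        "p_in,expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.6], [0.6]),
            ([0.01, 0.01, 0.01], [0.03, 0.03, 0.03]),
        ],
    )
    def test_holm_hand_stepdown(self, p_in, expected):
        assert co.holm_adjust(p_in) == pytest.approx(expected)

    def test_holm_domain_and_empty(self):
        assert co.holm_adjust([]) == []
        with pytest.raises(ValueError):
            co.holm_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            co.rank_sum_compare([], [1.0])
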