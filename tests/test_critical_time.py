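import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vfsim import (
    LONG_TERM,
    SHORT_TERM,
    PermutationSpec,
    all_permutations,
    compute_critical_times,
    compute_critical_times_cohort,
    find_critical_time_consecutive,
    find_critical_time_ground_truth,
    running_estimates,
    running_slope_and_adjust,
    simulate_core,
)
from vfsim.critical_time import estimate_reliability, estimate_variability
from vfsim.population import SubjectParams, subject_params
from vfsim.simulate import derive_permutation


# --- independent brute-force re-scan oracles ------------------------------


def brute_consecutive(times, est, tol):
    """Naive re-scan: for each candidate third visit, re-collect all defined
    estimates from scratch and test the trailing triplet."""
    out = float("nan")
    for v in range(len(est)):
        if math.isnan(est[v]):
            continue
        defined = [i for i in range(v + 1) if not math.isnan(est[i])]
        if len(defined) < 3 or defined[-1] != v:
            continue
        tri = [est[i] for i in defined[-3:]]
        if max(tri) - min(tri) <= tol * (sum(tri) / 3.0):
            return float(times[v])
    return out


def brute_ground_truth(times, est, truth, tol):
    for v in range(len(est)):
        if math.isnan(est[v]):
            continue
        defined = [i for i in range(v + 1) if not math.isnan(est[i])]
        if len(defined) < 3 or defined[-1] != v:
            continue
        tri = [est[i] for i in defined[-3:]]
        if all(abs(e - truth) <= tol * truth for e in tri):
            return float(times[v])
    return float("nan")


def _subject(**kw):
    base = dict(subject_id=0, md0=-4.0, slope=-0.5, sigma=1.0, reliability=0.9)
    base.update(kw)
    return SubjectParams(**base)


# --- running slope and adjustment -----------------------------------------


class TestRunningSlopeAndAdjust:
    def test_noiseless_linear_series_recovered_exactly(self):
        t = np.arange(6, dtype=float)
        y = (-4.0 - 0.5 * t)[:, None]
        slopes, adjusted = running_slope_and_adjust(t, y)
        np.testing.assert_allclose(slopes[1:], -0.5)
        assert adjusted[0] is None
        for a in adjusted[1:]:
            np.testing.assert_allclose(a, -4.0)

    def test_single_visit_undefined(self):
        slopes, adjusted = running_slope_and_adjust(
            np.array([0.0]), np.array([[-4.0]])
        )
        assert np.isnan(slopes[0]) and adjusted[0] is None

    def test_three_point_worked_example(self):
        """Hand normal-equations oracle: slope -0.6, adjusted
        {-4.0, -3.9, -4.0}."""
        t = np.array([0.0, 1.0, 2.0])
        y = np.array([[-4.0], [-4.5], [-5.2]])
        slopes, adjusted = running_slope_and_adjust(t, y)
        assert slopes[2] == pytest.approx(-0.6)
        np.testing.assert_allclose(adjusted[2], [-4.0, -3.9, -4.0])

    def test_single_distinct_time_undefined(self):
        """Two valid values at one visit time cannot support a slope."""
        t = np.array([0.0, 1.0])
        y = np.array([[-4.0, -4.2], [-5.0, -5.1]])
        valid = np.array([[True, True], [False, False]])
        slopes, adjusted = running_slope_and_adjust(t, y, valid)
        assert np.isnan(slopes).all()

    def test_refit_on_adjusted_values_is_flat(self, rng):
        """OLS residual property: adjusted values carry zero slope."""
        t = np.arange(12, dtype=float) * 0.25
        y = -3.0 - 0.8 * t[:, None] + rng.normal(0, 1.5, (12, 3))
        slopes, adjusted = running_slope_and_adjust(t, y)
        mask = np.ones_like(y, dtype=bool)
        for v in range(2, 12):
            tt = np.broadcast_to(t[: v + 1, None], (v + 1, 3))[mask[: v + 1]]
            refit = np.polyfit(tt, adjusted[v], 1)[0]
            assert refit == pytest.approx(0.0, abs=1e-10)


class TestPointEstimators:
    def test_variability_hand_values(self):
        assert estimate_variability([1.0, 1.0, 1.0]) == 0.0
        assert estimate_variability([0.0, 2.0]) == pytest.approx(math.sqrt(2), abs=1e-4)
        assert math.isnan(estimate_variability([1.0]))

    def test_reliability_hand_values(self):
        assert estimate_reliability([True] * 5) == 1.0
        assert estimate_reliability([True, True, True, False]) == 0.75
        assert estimate_reliability([False, False]) == 0.0
        assert math.isnan(estimate_reliability([]))


class TestWindowRules:
    def test_consecutive_first_qualifying_triplet(self):
        t = np.arange(5.0)
        est = np.array([1.00, 1.02, 1.01, 1.5, 1.5])
        assert find_critical_time_consecutive(t, est, 0.05) == 2.0

    def test_all_identical_including_zero_qualifies_at_third(self):
        t = np.arange(6.0)
        assert find_critical_time_consecutive(t, np.zeros(6), 0.05) == 2.0
        assert find_critical_time_consecutive(t, np.full(6, 7.0), 0.05) == 2.0

    def test_gap_skipped_without_reset(self):
        """An undefined visit between close estimates does not restart the
        3-visit count; the critical time is the third defined visit."""
        t = np.arange(6.0)
        est = np.array([1.0, np.nan, 1.01, np.nan, 1.02, np.nan])
        assert find_critical_time_consecutive(t, est, 0.05) == 4.0

    def test_censored_when_never_stable(self):
        t = np.arange(5.0)
        est = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        assert math.isnan(find_critical_time_consecutive(t, est, 0.05))

    def test_ground_truth_worked_example(self):
        """truth=1, 5%: series (0.94, 0.96, 1.00, 1.04) qualifies first at
        visits 1-3 (0.94 is outside the band)."""
        t = np.arange(4.0)
        est = np.array([0.94, 0.96, 1.00, 1.04])
        assert find_critical_time_ground_truth(t, est, 1.0, 0.05) == 3.0

    def test_ground_truth_immediate(self):
        t = np.arange(4.0)
        assert find_critical_time_ground_truth(t, np.ones(4), 1.0, 0.05) == 2.0

    def test_invalid_inputs(self):
        t = np.arange(3.0)
        with pytest.raises(ValueError):
            find_critical_time_consecutive(t, np.ones(3), -0.1)
        with pytest.raises(ValueError):
            find_critical_time_ground_truth(t, np.ones(3), 0.0, 0.05)

    def test_oracle_equivalence_thousand_random_gapped_series(self):
        """Production scan agrees with the naive O(n^2) re-scan on 1000
        random series with gaps, for both window rules."""
        gen = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(gen.integers(1, 40))
            est = np.abs(gen.normal(1.0, 0.4, n))
            est[gen.random(n) < 0.25] = np.nan
            t = np.cumsum(gen.integers(1, 4, n)).astype(float)
            tol = float(gen.uniform(0.01, 0.4))
            truth = float(gen.uniform(0.5, 1.5))
            a = find_critical_time_consecutive(t, est, tol)
            b = brute_consecutive(t, est, tol)
            assert (math.isnan(a) and math.isnan(b)) or a == b
            a = find_critical_time_ground_truth(t, est, truth, tol)
            b = brute_ground_truth(t, est, truth, tol)
            assert (math.isnan(a) and math.isnan(b)) or a == b

    @given(
        data=st.lists(
            st.one_of(st.none(), st.floats(0.1, 10.0)), min_size=1, max_size=30
        ),
        tol=st.floats(0.01, 0.5),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_consecutive_rule_matches_oracle_property(self, data, tol):
        est = np.array([np.nan if v is None else v for v in data])
        t = np.arange(len(est), dtype=float)
        a = find_critical_time_consecutive(t, est, tol)
        b = brute_consecutive(t, est, tol)
        assert (math.isnan(a) and math.isnan(b)) or a == b


class TestComputeCriticalTimes:
    def test_floor_case_perfect_subject(self, rng):
        """reliability=1 and zero noise: TcR at day 2; variability defined
        from day 1 with one test/visit, so TcV at day 3 (zero-spread triplet
        qualifies)."""
        p = _subject(slope=0.0, sigma=0.0, reliability=1.0)
        core = simulate_core(p, SHORT_TERM, rng)
        ct = compute_critical_times(core, PermutationSpec(1, 1), p, "short_term")
        assert ct.tcr == 2.0
        assert ct.tcv == 3.0

    def test_long_term_floor_is_third_visit(self, rng):
        p = _subject(slope=0.0, sigma=1e-9, reliability=1.0)
        core = simulate_core(p, LONG_TERM, rng)
        for m, expected in [(1, 0.5), (4, 2.0)]:
            ct = compute_critical_times(core, PermutationSpec(1, m), p, "long_term")
            assert ct.tcr == expected

    def test_no_critical_time_before_third_eligible_visit(self, small_population, small_short_cohort):
        for spec in (PermutationSpec(1, 1), PermutationSpec(4, 2)):
            df = compute_critical_times_cohort(
                small_short_cohort, spec, small_population, "short_term"
            )
            m = spec.interval_multiplier
            # reliability estimates exist from visit 0: third visit is at 2m days
            assert (df["tcr"].dropna() >= 2 * m).all()
            assert (df["tgr"].dropna() >= 2 * m).all()
            # variability needs >=2 valid values first
            assert (df["tcv"].dropna() >= 2 * m).all()

    def test_mode_controls_detrending(self, rng):
        """A strongly progressing subject: raw cumulative SD is inflated by
        the trend, the long-term normalization removes it."""
        p = _subject(slope=-2.0, sigma=0.5, reliability=1.0)
        core = simulate_core(p, LONG_TERM, rng)
        detrended = running_estimates(core, detrend=True)
        raw = running_estimates(core, detrend=False)
        assert raw.variability[-1] > 2.0
        assert detrended.variability[-1] == pytest.approx(0.5, abs=0.1)

    def test_diffs_defined_iff_detected(self, small_population, small_long_cohort):
        df = compute_critical_times_cohort(
            small_long_cohort, PermutationSpec(1, 4), small_population, "long_term"
        )
        assert df["var_at_tcv_db"].notna().equals(df["tcv"].notna())
        assert df["diff_rel"].notna().equals(df["tcr"].notna())

    def test_invalid_mode_and_tolerance(self, small_population, small_long_cohort):
        with pytest.raises(ValueError):
            compute_critical_times_cohort(
                small_long_cohort, PermutationSpec(1, 1), small_population, "weekly"
            )
        with pytest.raises(ValueError):
            compute_critical_times_cohort(
                small_long_cohort, PermutationSpec(1, 1), small_population,
                "long_term", tolerance=0.0,
            )


class TestCohortPathEquivalence:
    @pytest.mark.parametrize("family", ["long_term", "short_term"])
    def test_vectorised_matches_per_subject(
        self, family, small_population, small_long_cohort, small_short_cohort
    ):
        cohort = small_long_cohort if family == "long_term" else small_short_cohort
        for spec in (PermutationSpec(1, 1), PermutationSpec(4, 2), PermutationSpec(2, 4)):
            df = compute_critical_times_cohort(cohort, spec, small_population, family)
            for i in range(0, cohort.n_subjects, 23):
                ct = compute_critical_times(
                    cohort.subject(i), spec, subject_params(small_population.iloc[i]), family
                )
                row = df.iloc[i]
                for field, col in [
                    ("tcv", "tcv"), ("tgv", "tgv"), ("tcr", "tcr"), ("tgr", "tgr"),
                    ("var_at_tcv", "var_at_tcv_db"), ("rel_at_tcr", "rel_at_tcr"),
                ]:
                    a, b = getattr(ct, field), row[col]
                    assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-9), (
                        family, spec.label, i, field,
                    )


class TestToleranceMonotonicity:
    def test_wider_tolerance_never_delays_detection(
        self, small_population, small_long_cohort
    ):
        """Raising the rolling-window tolerance from 5% to 10% can only move
        TcV/TcR earlier (or turn censored into detected)."""
        for spec in all_permutations()[:6]:
            tight = compute_critical_times_cohort(
                small_long_cohort, spec, small_population, "long_term", tolerance=0.05
            )
            loose = compute_critical_times_cohort(
                small_long_cohort, spec, small_population, "long_term", tolerance=0.10
            )
            for col in ("tcv", "tcr"):
                a, b = tight[col], loose[col]
                both = a.notna() & b.notna()
                assert (b[both] <= a[both]).all()
                # detected at 5% implies detected at 10%
                assert not (a.notna() & b.isna()).any()


class TestParameterRecovery:
    def test_short_term_end_of_series_variability_unbiased(self):
        """Over subjects with sigma in a narrow band, the final 4-test daily
        variability estimate matches sigma up to the known small-sample SD
        bias (112 valid draws at reliability 1)."""
        import pandas as pd
        from vfsim import simulate_cohort

        n = 400
        pop = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "md0_db": -4.0,
                "slope_db_per_year": 0.0,
                "sigma_db": 1.5,
                "reliability": 1.0,
            }
        )
        cohort = simulate_cohort(pop, SHORT_TERM, np.random.SeedSequence(11))
        from vfsim.critical_time import _cohort_running_stats

        var, _, _ = _cohort_running_stats(cohort, detrend=False)
        final = var[:, -1]
        # E[s] = sigma * c4(n); c4(112) ~ 1 - 1/(4*112)
        c4 = 1 - 1 / (4 * 112)
        assert final.mean() == pytest.approx(1.5 * c4, abs=0.02)
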