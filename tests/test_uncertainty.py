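"""Deviation statistics, validation tests, expanded and MC uncertainties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbkit.core import DeltaObservation
from ssbkit.uncertainty import (
    FLAG_PRECISION,
    FLAG_REPRODUCIBILITY,
    McConfig,
    SampleSeries,
    SSBError,
    build_report,
    deviations,
    expanded_uncertainty,
    monte_carlo_sd,
)
from ssbkit.uncertainty import test_normality as normality_p
from ssbkit.uncertainty import test_zero_mean as zero_mean_p


def series(label, values, prop_se=0.0, reference=None):
    ses = [prop_se] * len(values) if np.isscalar(prop_se) else list(prop_se)
    obs = tuple(
        DeltaObservation(label, float(v), float(s), i)
        for i, (v, s) in enumerate(zip(values, ses))
    )
    return SampleSeries(label, obs, reference_delta=reference)


class TestDeviations:
    def test_single_measurement_against_literature_value(self):
        # one delta of -0.70 permil against a reference of -0.68 permil
        dev = deviations(series("SELM-1", [-0.70], reference=-0.68))
        assert dev.deviations[0] == pytest.approx(-0.02, abs=1e-12)
        assert dev.n == 1 and math.isnan(dev.sd)

    def test_mean_substitution_zeroes_the_mean_deviation_exactly(self):
        dev = deviations(series("BC210a", [-2.2, -2.3, -2.2]))
        assert dev.mean == 0.0

    def test_constant_series_equal_to_reference(self):
        dev = deviations(series("X", [0.5, 0.5, 0.5], reference=0.5))
        assert np.all(dev.deviations == 0.0) and dev.sd == 0.0

    def test_sample_sd_uses_n_minus_one(self):
        # hand: values 0.1, 0.4, 1.0 vs 0 -> var = (0.16+0.01+0.25)/2 = 0.21
        dev = deviations(series("X", [0.1, 0.4, 1.0], reference=0.5))
        assert dev.sd == pytest.approx(math.sqrt(0.21), rel=1e-12)

    def test_mean_is_mean_delta_minus_reference(self):
        dev = deviations(series("X", [1.0, 2.0, 4.0], reference=1.5))
        assert dev.mean == pytest.approx((7.0 / 3.0) - 1.5, rel=1e-15)

    def test_empty_series_rejected(self):
        with pytest.raises(SSBError):
            SampleSeries("X", ())

    def test_reference_source_bookkeeping(self):
        assert series("X", [1.0], reference=0.5).reference_source == "literature"
        s = series("X", [1.0, 3.0])
        assert s.reference_source == "sample_mean"
        assert s.reference_delta == 2.0


class TestNormalityTest:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_normal_sample_is_not_rejected(self, seed):
        x = np.random.default_rng(seed).normal(0, 0.07, 200)
        assert normality_p(x) > 0.001

    def test_constant_sample_is_not_applicable(self):
        assert math.isnan(normality_p(np.zeros(10)))

    @pytest.mark.parametrize("n", [2, 5001])
    def test_outside_validity_range_is_not_applicable(self, n):
        assert math.isnan(normality_p(np.linspace(0, 1, n)))

    def test_bimodal_sample_rejected_and_matches_r_oracle(self):
        # R: shapiro.test(c(rep(-1,50), rep(1,50))) -> W=0.636401, p=2.233602e-14
        x = np.r_[np.full(50, -1.0), np.full(50, 1.0)]
        p = normality_p(x)
        assert p < 0.001
        assert p == pytest.approx(2.233602e-14, rel=1e-4)


class TestZeroMeanTest:
    def test_mean_substituted_series_gives_p_one(self):
        dev = deviations(series("X", [-2.2, -2.3, -2.27, -2.18]))
        assert round(zero_mean_p(dev.deviations), 4) == 1.0

    def test_symmetric_set_gives_t_zero_p_one(self):
        assert zero_mean_p(np.array([-1.0, 0.0, 1.0])) == 1.0

    def test_against_textbook_t_formula(self):
        # x = {1, 1.1, 0.9, 1.05}: t = mean/(s/sqrt(4)) = 23.7143717726,
        # p = 2*P(T_3 > t) = 1.6430951783e-4 (hand evaluation)
        p = zero_mean_p(np.array([1.0, 1.1, 0.9, 1.05]))
        assert p == pytest.approx(1.6430951783288385e-4, rel=1e-10)

    def test_degenerate_variance_is_not_applicable(self):
        assert math.isnan(zero_mean_p(np.full(5, 0.3)))
        assert math.isnan(zero_mean_p(np.array([0.1])))


class TestExpandedUncertainty:
    def test_joint_reproducibility_value_rounds_to_0_14(self):
        assert round(expanded_uncertainty(0.0701), 2) == 0.14

    def test_joint_mc_value_rounds_to_0_19(self):
        assert round(expanded_uncertainty(0.0963), 2) == 0.19

    def test_zero_sd_gives_zero(self):
        assert expanded_uncertainty(0.0) == 0.0

    def test_uses_exact_normal_quantile(self):
        assert expanded_uncertainty(1.0) == pytest.approx(1.959963985, rel=1e-9)

    @pytest.mark.parametrize("coverage", [0.0, 1.0, -0.5, 1.7])
    def test_invalid_coverage_rejected(self, coverage):
        with pytest.raises(SSBError):
            expanded_uncertainty(0.1, coverage)


class TestMonteCarloSD:
    def test_zero_prop_se_reduces_to_plain_sd_exactly(self):
        s = series("X", [0.1, -0.2, 0.3, 0.05], prop_se=0.0, reference=0.0)
        sd = deviations(s).sd
        for runs in (1, 10**6):
            mc = monte_carlo_sd([s], McConfig(runs=runs, seed=0))
            assert mc.per_series["X"] == sd
            assert mc.pooled == sd

    def test_variance_addition_limit(self, rng):
        # constant prop_se sigma: E[SD_mc] -> sqrt(SD^2 + sigma^2)
        vals = rng.normal(0.0, 0.07, 500)
        s = series("X", vals, prop_se=0.06, reference=0.0)
        mc = monte_carlo_sd([s], McConfig(runs=10**4, seed=7))
        expected = math.hypot(deviations(s).sd, 0.06)
        assert mc.per_series["X"] == pytest.approx(expected, rel=0.02)

    def test_seeded_repeat_is_bit_identical(self, rng):
        s = series("X", rng.normal(0, 0.1, 30), prop_se=0.05, reference=0.0)
        a = monte_carlo_sd([s], McConfig(runs=2000, seed=11))
        b = monte_carlo_sd([s], McConfig(runs=2000, seed=11))
        assert a == b

    def test_result_independent_of_series_ordering(self, rng):
        s1 = series("A", rng.normal(0, 0.1, 10), prop_se=0.05, reference=0.0)
        obs2 = tuple(
            DeltaObservation("B", float(v), 0.08, i + 100)
            for i, v in enumerate(rng.normal(0, 0.1, 8))
        )
        s2 = SampleSeries("B", obs2, reference_delta=0.0)
        fwd = monte_carlo_sd([s1, s2], McConfig(runs=500, seed=3))
        rev = monte_carlo_sd([s2, s1], McConfig(runs=500, seed=3))
        assert fwd.per_series == rev.per_series
        assert fwd.pooled == rev.pooled

    def test_increasing_one_prop_se_does_not_decrease_sd_mc(self, rng):
        vals = rng.normal(0, 0.1, 20)
        lo = series("X", vals, prop_se=[0.02] * 20, reference=0.0)
        hi_ses = [0.02] * 20
        hi_ses[7] = 0.2
        hi = series("X", vals, prop_se=hi_ses, reference=0.0)
        a = monte_carlo_sd([lo], McConfig(runs=4000, seed=5)).pooled
        b = monte_carlo_sd([hi], McConfig(runs=4000, seed=5)).pooled
        assert b >= a

    @given(c=st.floats(1e-2, 1e2))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        vals = [0.11, -0.07, 0.19, 0.02, -0.13]
        base = series("X", vals, prop_se=0.05, reference=0.0)
        scaled = series("X", [v * c for v in vals], prop_se=0.05 * c, reference=0.0)
        a = monte_carlo_sd([base], McConfig(runs=300, seed=9)).pooled
        b = monte_carlo_sd([scaled], McConfig(runs=300, seed=9)).pooled
        assert b == pytest.approx(c * a, rel=1e-12)

    def test_estimator_converges_in_run_count(self, rng):
        s = series("X", rng.normal(0, 0.07, 20), prop_se=0.06, reference=0.0)
        a = monte_carlo_sd([s], McConfig(runs=10**5, seed=1)).pooled
        b = monte_carlo_sd([s], McConfig(runs=10**6, seed=2)).pooled
        assert abs(a / b - 1) < 0.005

    def test_missing_prop_se_is_an_error(self):
        obs = (DeltaObservation("X", 0.1, float("nan"), 0),)
        s = SampleSeries("X", obs, reference_delta=0.0)
        with pytest.raises(SSBError, match="seq_index 0"):
            monte_carlo_sd([s], McConfig(runs=10, seed=0))


class TestBuildReport:
    def test_degenerate_sample_is_reproducibility_dominated(self):
        s = series("X", [0.5, 0.5, 0.5], prop_se=0.0, reference=0.5)
        rep = build_report([s], McConfig(runs=10, seed=0))
        row = rep.per_sample[0]
        assert row.sd_delta == 0.0 and row.sd_delta_mc == 0.0
        assert row.u == 0.0 and row.u_mc == 0.0
        assert row.flag == FLAG_REPRODUCIBILITY

    def test_joint_n_is_the_sum_of_per_sample_n(self, rng):
        s1 = series("A", rng.normal(0, 0.1, 12), prop_se=0.05, reference=0.0)
        s2 = series("B", rng.normal(0, 0.1, 7), prop_se=0.05, reference=0.0)
        rep = build_report([s1, s2], McConfig(runs=100, seed=0))
        assert rep.joint.n == 19 == sum(r.n for r in rep.per_sample)

    def test_u_columns_are_z_times_sd(self, rng):
        s = series("A", rng.normal(0, 0.1, 10), prop_se=0.05, reference=0.0)
        rep = build_report([s], McConfig(runs=200, seed=1))
        for row in rep.rows:
            assert row.u == pytest.approx(expanded_uncertainty(row.sd_delta), rel=1e-15)
            assert row.u_mc == pytest.approx(
                expanded_uncertainty(row.sd_delta_mc), rel=1e-15
            )

    def test_mc_sd_not_below_plain_sd(self, rng):
        s = series("A", rng.normal(0, 0.08, 40), prop_se=0.05, reference=0.0)
        rep = build_report([s], McConfig(runs=5000, seed=2))
        for row in rep.rows:
            assert row.sd_delta_mc >= row.sd_delta

    def test_low_precision_sample_is_flagged(self, rng):
        # small reproducibility spread but large per-measurement errors,
        # the SCo-1-like pattern: SD_mc / SD well above the threshold
        vals = rng.normal(0.19, 0.04, 9)
        s = series("SCo-1", vals, prop_se=0.15, reference=0.175)
        rep = build_report([s], McConfig(runs=4000, seed=3))
        row = rep.per_sample[0]
        assert row.sd_delta_mc / row.sd_delta > 3
        assert row.flag == FLAG_PRECISION

    def test_duplicate_labels_rejected(self):
        s1 = series("A", [0.1, 0.2], reference=0.0)
        s2 = series("A", [0.3, 0.4], reference=0.0)
        with pytest.raises(SSBError, match="duplicate"):
            build_report([s1, s2], McConfig(runs=10, seed=0))

    def test_mean_substituted_row_reports_p_one_and_no_reference(self, rng):
        s = series("B", rng.normal(-2.2, 0.07, 13))
        rep = build_report([s], McConfig(runs=100, seed=4))
        row = rep.per_sample[0]
        assert row.reference_delta is None
        assert row.deviation_avg == 0.0
        assert round(row.ttest_p, 4) == 1.0

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_report_scale_equivariance(self, c):
        vals = [0.11, -0.07, 0.19, 0.02, -0.13, 0.08]
        a = build_report(
            [series("X", vals, prop_se=0.05, reference=0.02)],
            McConfig(runs=200, seed=6),
        ).joint
        b = build_report(
            [series("X", [v * c for v in vals], prop_se=0.05 * c, reference=0.02 * c)],
            McConfig(runs=200, seed=6),
        ).joint
        for attr in ("deviation_avg", "sd_delta", "sd_delta_mc", "u", "u_mc"):
            assert getattr(b, attr) == pytest.approx(c * getattr(a, attr), rel=1e-9)
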