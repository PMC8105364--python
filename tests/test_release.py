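"""Degradation correction and power-law fitting of release studies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gfelute as g
from gfelute.errors import (
    InconsistentMassError,
    InsufficientDataError,
    InvalidParameterError,
    SchemaError,
)


def make_study(times, concs, volume=1.0, area=1.0, wash=0.0):
    return g.ReleaseStudy(
        condition_label="c", replicate_id="r1", vial_volume=volume,
        substrate_area=area, samples=tuple(zip(times, concs)), wash_recovery=wash,
    )


class TestIntervalReleases:
    def test_amount_is_concentration_times_volume(self):
        study = make_study([24.0, 48.0], [2.0, 1.0])
        out = g.interval_releases(study)
        assert out == [((0.0, 24.0), 2.0), ((24.0, 48.0), 1.0)]

    def test_volume_scaling(self):
        study = make_study([24.0], [4.0], volume=0.5)
        assert g.interval_releases(study)[0][1] == pytest.approx(2.0)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(SchemaError):
            make_study([24.0, 24.0], [1.0, 1.0])


class TestCorrectionFactor:
    def test_half_life_interval_value(self, k_ref):
        # k*dt = ln 2 exactly when the interval spans one half-life
        assert g.correction_factor(k_ref, 22.75) == pytest.approx(1.386294, abs=1e-6)

    def test_no_degradation_limit(self):
        assert g.correction_factor(0.0, 24.0) == 1.0

    def test_large_argument_asymptote(self):
        # for k*dt >> 1 the factor approaches k*dt itself
        assert g.correction_factor(1.0, 20.0) == pytest.approx(20.0, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(1e-6, 30.0))
    def test_factor_at_least_one_and_increasing(self, x):
        f = g.correction_factor(x, 1.0)
        assert f >= 1.0
        assert g.correction_factor(x * 1.01, 1.0) > f

    def test_continuity_at_zero(self):
        assert g.correction_factor(1e-12, 1.0) == pytest.approx(1.0, abs=1e-9)


class TestDegradationCorrect:
    def test_zero_rate_is_identity(self):
        intervals = [((0.0, 24.0), 2.0), ((24.0, 48.0), 1.0)]
        corr = g.degradation_correct(intervals, k=0.0)
        assert corr.interval_true_release == (2.0, 1.0)
        assert corr.cumulative == ((24.0, 2.0), (48.0, 3.0))

    def test_corrected_never_below_measured(self, k_ref):
        intervals = [((0.0, 8.0), 1.0), ((8.0, 48.0), 2.0), ((48.0, 96.0), 0.5)]
        corr = g.degradation_correct(intervals, k=k_ref)
        for (iv, measured), true in zip(intervals, corr.interval_true_release):
            assert true >= measured

    def test_cumulative_non_decreasing(self, k_ref):
        intervals = [((0.0, 8.0), 0.0), ((8.0, 48.0), 2.0), ((48.0, 96.0), 0.0)]
        corr = g.degradation_correct(intervals, k=k_ref)
        assert np.all(np.diff(corr.cumulative_ng) >= 0)

    def test_midpoint_variant_close_for_small_kdt(self, k_ref):
        intervals = [((0.0, 1.0), 1.0)]
        exact = g.degradation_correct(intervals, k=k_ref)
        mid = g.degradation_correct(intervals, k=k_ref, midpoint=True)
        assert mid.interval_true_release[0] == pytest.approx(
            exact.interval_true_release[0], rel=1e-4
        )

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            g.degradation_correct([((0.0, 1.0), 1.0)], k=-0.1)


class TestMInfinity:
    def test_cumulative_plus_wash(self):
        corr = g.degradation_correct([((0.0, 96.0), 4.71)], k=0.0)
        assert g.m_infinity(corr, 6.7) == pytest.approx(11.41)

    def test_zero_wash(self):
        corr = g.degradation_correct([((0.0, 96.0), 3.0)], k=0.0)
        assert g.m_infinity(corr, 0.0) == pytest.approx(3.0)

    def test_empty_cumulative_rejected(self):
        corr = g.CorrectedRelease((), (), 0.0)
        with pytest.raises(InsufficientDataError):
            g.m_infinity(corr, 1.0)


class TestFitPowerLaw:
    @pytest.mark.parametrize("K,n", [(0.1, 0.3), (0.01, 1.0)])
    def test_exact_log_log_data_recovered(self, K, n):
        t = np.array([1.0, 8.0, 24.0, 96.0])
        m_inf = 10.0
        cum = m_inf * K * t**n
        intervals = np.diff(np.concatenate([[0.0], cum]))
        corr = g.CorrectedRelease(tuple(intervals), tuple(zip(t, cum)), 0.0)
        fit = g.fit_power_law(corr, m_inf)
        assert fit.K == pytest.approx(K, rel=1e-10)
        assert fit.n == pytest.approx(n, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slow_release_exponent_regime(self):
        """Exponents well below 0.5 (anomalous slow release) round-trip."""
        t = np.array([1.0, 4.0, 24.0, 96.0])
        cum = 8.0 * 0.2 * t**0.25
        corr = g.CorrectedRelease(tuple(np.diff(np.r_[0.0, cum])), tuple(zip(t, cum)), 0.0)
        fit = g.fit_power_law(corr, 8.0)
        assert fit.n == pytest.approx(0.25, rel=1e-9)

    def test_nonlinear_mode_matches_on_exact_data(self):
        t = np.array([1.0, 8.0, 24.0, 96.0])
        cum = 10.0 * 0.1 * t**0.3
        corr = g.CorrectedRelease(tuple(np.diff(np.r_[0.0, cum])), tuple(zip(t, cum)), 0.0)
        fit = g.fit_power_law(corr, 10.0, nonlinear=True)
        assert fit.K == pytest.approx(0.1, rel=1e-6)
        assert fit.n == pytest.approx(0.3, rel=1e-6)

    def test_fraction_above_one_rejected(self):
        corr = g.CorrectedRelease((5.0, 7.0), ((24.0, 5.0), (48.0, 12.0)), 0.0)
        with pytest.raises(InconsistentMassError):
            g.fit_power_law(corr, 10.0)

    def test_too_few_points_rejected(self):
        corr = g.CorrectedRelease((1.0,), ((24.0, 1.0),), 0.0)
        with pytest.raises(InsufficientDataError):
            g.fit_power_law(corr, 10.0)


class TestPredictRelease:
    def test_value_at_unit_time(self, powerlaw_source):
        f = powerlaw_source
        assert g.predict_release(f, 1.0) == pytest.approx(f.K * f.M_infinity)

    def test_zero_at_time_zero(self, powerlaw_source):
        assert g.predict_release(powerlaw_source, 0.0) == 0.0

    def test_saturates_at_m_infinity(self):
        fit = g.PowerLawFit(K=0.5, n=1.0, M_infinity=10.0, r_squared=1.0,
                            fit_domain=(0.0, 96.0))
        assert g.predict_release(fit, 1000.0) == pytest.approx(10.0)

    @settings(derandomize=True, max_examples=25)
    @given(t1=st.floats(0.0, 200.0), t2=st.floats(0.0, 200.0))
    def test_monotone_and_bounded(self, t1, t2):
        fit = g.PowerLawFit(K=0.05, n=0.3, M_infinity=10.0, r_squared=1.0,
                            fit_domain=(0.0, 96.0))
        lo, hi = sorted([t1, t2])
        r_lo = g.predict_release(fit, lo)
        r_hi = g.predict_release(fit, hi)
        assert r_lo <= r_hi <= fit.M_infinity


class TestPipelineRoundTrip:
    def test_correct_then_fit_recovers_truth(self):
        """Noiseless generated study -> exact correction -> exact recovery."""
        spec = g.ReleaseSpec(cv=0.0, seed=0)
        study = g.gen_release_study(spec)[0]
        corr = g.correct_study(study, k=spec.k_true)
        m_inf = g.m_infinity(corr, study.wash_recovery)
        fit = g.fit_power_law(corr, m_inf)
        assert fit.K == pytest.approx(spec.K, rel=1e-6)
        assert fit.n == pytest.approx(spec.n, rel=1e-6)
        assert m_inf == pytest.approx(spec.M_infinity, rel=1e-9)
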