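"""Well-concentration simulation: eluting source, bolus dosing, tables."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import gfelute as g
from gfelute.errors import InvalidParameterError, SchemaError


def quadrature_oracle(fit, system, k, t):
    """Independent evaluation of C(t) = (1/V) int_0^t R'(s) e^{-k(t-s)} ds.

    Uses integration by parts (R(0) = 0) so the integrand is smooth:
    C(t) = [R(t) - k * int_0^t R(s) e^{-k(t-s)} ds] / V.
    """
    def R(s):
        return system.surface_area * fit.M_infinity * min(1.0, fit.K * s**fit.n)

    if t == 0:
        return 0.0
    val, _ = quad(lambda s: R(s) * math.exp(-k * (t - s)), 0.0, t, limit=200)
    return (R(t) - k * val) / system.media_volume


class TestSimulateEluting:
    def test_matches_quadrature(self, powerlaw_source, culture_system, k_ref):
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.05)
        prof = g.simulate_eluting(powerlaw_source, culture_system, cfg)
        ts = np.linspace(0.5, 96.0, 30)
        sim = np.interp(ts, prof.times, prof.concentrations)
        exact = np.array([quadrature_oracle(powerlaw_source, culture_system, k_ref, t)
                          for t in ts])
        assert np.max(np.abs(sim - exact)) / np.max(exact) < 1e-3

    def test_mass_conservation_without_degradation(self, powerlaw_source, culture_system):
        cfg = g.SimulationConfig(k=0.0, t_end=96.0, dt=0.05)
        prof = g.simulate_eluting(powerlaw_source, culture_system, cfg)
        released = culture_system.surface_area * np.array(
            [g.predict_release(powerlaw_source, t) for t in prof.times]
        )
        resid = np.abs(culture_system.media_volume * prof.concentrations - released)
        assert np.max(resid) / np.max(released) < 1e-9

    def test_no_source_no_concentration(self, culture_system, k_ref):
        fit = g.PowerLawFit(K=1e-300, n=0.3, M_infinity=10.0, r_squared=1.0,
                            fit_domain=(0.0, 96.0))
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.5)
        prof = g.simulate_eluting(fit, culture_system, cfg)
        assert np.max(prof.concentrations) < 1e-290

    def test_step_halving_converged(self, powerlaw_source, culture_system, k_ref):
        coarse = g.simulate_eluting(powerlaw_source, culture_system,
                                    g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.05))
        fine = g.simulate_eluting(powerlaw_source, culture_system,
                                  g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.025))
        ts = np.linspace(0.5, 96.0, 50)
        c1 = np.interp(ts, coarse.times, coarse.concentrations)
        c2 = np.interp(ts, fine.times, fine.concentrations)
        assert np.max(np.abs(c1 - c2)) / np.max(c1) < 1e-3

    def test_study_area_scaling(self, culture_system, k_ref):
        """M_infinity given per 2 cm² study substrate halves the per-cm² source."""
        fit = g.PowerLawFit(K=0.05, n=0.3, M_infinity=10.0, r_squared=1.0,
                            fit_domain=(0.0, 96.0))
        cfg1 = g.SimulationConfig(k=k_ref, t_end=48.0, dt=0.1, study_area=1.0)
        cfg2 = g.SimulationConfig(k=k_ref, t_end=48.0, dt=0.1, study_area=2.0)
        p1 = g.simulate_eluting(fit, culture_system, cfg1)
        p2 = g.simulate_eluting(fit, culture_system, cfg2)
        assert np.allclose(p1.concentrations, 2.0 * p2.concentrations)

    def test_invalid_step_rejected(self, k_ref):
        with pytest.raises(InvalidParameterError):
            g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.0)


class TestSimulateExogenous:
    def test_two_dose_trough_and_peak(self, culture_system, k_ref):
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.05)
        doses = [g.DoseEvent(0.0, 16.0), g.DoseEvent(48.0, 16.0)]
        prof = g.simulate_exogenous(doses, culture_system, cfg)
        assert prof.value_at(48.0, side="pre") == pytest.approx(3.71, abs=0.02)
        assert prof.value_at(48.0, side="post") == pytest.approx(19.71, abs=0.02)

    def test_single_dose_equals_closed_form_decay(self, culture_system, k_ref):
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.5)
        prof = g.simulate_exogenous([g.DoseEvent(0.0, 10.0)], culture_system, cfg)
        expected = g.decay_concentration(10.0, k_ref, prof.times)
        assert np.allclose(prof.concentrations, expected, rtol=1e-14)

    def test_no_decay_staircase(self, culture_system):
        cfg = g.SimulationConfig(k=0.0, t_end=96.0, dt=1.0)
        doses = [g.DoseEvent(0.0, 4.0), g.DoseEvent(48.0, 4.0)]
        prof = g.simulate_exogenous(doses, culture_system, cfg)
        assert prof.value_at(24.0) == pytest.approx(4.0)
        assert prof.value_at(72.0) == pytest.approx(8.0)

    def test_superposition_of_schedules(self, culture_system, k_ref):
        """The decay ODE is linear: profiles add across dose schedules."""
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.5)
        d1 = [g.DoseEvent(0.0, 8.0)]
        d2 = [g.DoseEvent(48.0, 4.0)]
        p1 = g.simulate_exogenous(d1, culture_system, cfg)
        p2 = g.simulate_exogenous(d2, culture_system, cfg)
        both = g.simulate_exogenous(d1 + d2, culture_system, cfg)
        assert np.allclose(both.concentrations, p1.concentrations + p2.concentrations)

    def test_unsorted_doses_rejected(self, culture_system, k_ref):
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.5)
        with pytest.raises(SchemaError):
            g.simulate_exogenous(
                [g.DoseEvent(48.0, 4.0), g.DoseEvent(0.0, 4.0)], culture_system, cfg
            )


class TestProfileStatsAndTable:
    def test_monotone_decay_extremes(self, culture_system, k_ref):
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.5)
        prof = g.simulate_exogenous([g.DoseEvent(0.0, 16.0)], culture_system, cfg)
        stats = g.profile_stats(prof, after=0.0)
        assert stats.max_conc == pytest.approx(16.0)
        assert stats.t_max == 0.0
        assert stats.t_min == 96.0

    def test_after_beyond_span_rejected(self, culture_system, k_ref):
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.5)
        prof = g.simulate_exogenous([g.DoseEvent(0.0, 16.0)], culture_system, cfg)
        with pytest.raises(InvalidParameterError):
            g.profile_stats(prof, after=96.0)

    def test_table_reads_pre_dose_values(self, culture_system, k_ref):
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.05)
        profiles = {
            "8 ng/mL": g.simulate_exogenous(
                [g.DoseEvent(0.0, 8.0), g.DoseEvent(48.0, 8.0)], culture_system, cfg),
            "4 ng/mL": g.simulate_exogenous(
                [g.DoseEvent(0.0, 4.0), g.DoseEvent(48.0, 4.0)], culture_system, cfg),
        }
        table = g.condition_table(profiles, [48.0, 96.0])
        assert table.loc["8 ng/mL", "t=48h"] == pytest.approx(1.86, abs=0.02)
        assert table.loc["8 ng/mL", "t=96h"] == pytest.approx(2.28, abs=0.02)
        assert table.loc["4 ng/mL", "t=48h"] == pytest.approx(0.93, abs=0.02)
        assert table.loc["4 ng/mL", "t=96h"] == pytest.approx(1.14, abs=0.02)

    def test_rounded_rendering(self, culture_system, k_ref):
        cfg = g.SimulationConfig(k=k_ref, t_end=96.0, dt=0.05)
        profiles = {"x": g.simulate_exogenous([g.DoseEvent(0.0, 16.0)],
                                              culture_system, cfg)}
        table = g.condition_table(profiles, [48.0], rounded=True)
        assert table.loc["x", "t=48h"] == 3.71


class TestPopulationDoublings:
    def test_one_doubling(self):
        assert g.population_doublings(1000, 2000) == pytest.approx(1.0)

    def test_identity(self):
        assert g.population_doublings(1000, 1000) == 0.0

    def test_fibroblast_expansion(self):
        # 9387 -> 42560 cells/cm² over two days of culture
        assert g.population_doublings(9387, 42560) == pytest.approx(2.18, abs=0.005)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            g.population_doublings(0, 100)
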