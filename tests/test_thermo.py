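"""Multi-state thermodynamics: ΔG(P), populations, ensemble shift, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hpcoil as hp
from hpcoil.pressure import PressureSeries, fit_series
from hpcoil.simulate import SimulationSpec, gen_series
from hpcoil.thermo import (
    GAS_CONSTANT,
    MultiStateModel,
    StateShift,
    TransitionThermo,
    compressibility_ratio,
    compression_correct,
    deltaG,
    ensemble_shift,
    fit_two_state,
    populations,
)

RT_283 = GAS_CONSTANT * 283.0 / 1e3  # kJ/mol


class TestDeltaG:
    def test_zero_pressure_offset(self):
        assert deltaG(TransitionThermo(dG0=5.0, dV0=-50.0), 0.0) == 5.0

    def test_ml_mpa_is_joule(self):
        # 5 kJ/mol - 50 mL/mol * 100 MPa = 5 kJ - 5 kJ = 0
        t = TransitionThermo(dG0=5.0, dV0=-50.0, dVdP=0.0)
        assert deltaG(t, 100.0) == pytest.approx(0.0)

    def test_linear_when_dvdp_zero(self):
        t = TransitionThermo(dG0=2.0, dV0=-30.0)
        g = [deltaG(t, dp) for dp in (0, 50, 100)]
        assert g[2] - g[1] == pytest.approx(g[1] - g[0])

    def test_quadratic_term(self):
        t = TransitionThermo(dG0=0.0, dV0=0.0, dVdP=20.0)  # mL/mol/GPa
        # 0.5 * 20e-3 mL/mol/MPa * (100 MPa)^2 = 100 J/mol
        assert deltaG(t, 100.0) == pytest.approx(0.1)


class TestPopulations:
    def test_single_state(self):
        m = MultiStateModel(transitions=[])
        assert populations(m, 50.0).tolist() == [1.0]

    def test_symmetric_two_state(self):
        m = MultiStateModel(transitions=[TransitionThermo(dG0=0.0, dV0=0.0)])
        assert populations(m, 0.0) == pytest.approx([0.5, 0.5])

    def test_rt_ln3_gives_three_to_one(self):
        m = MultiStateModel(
            transitions=[TransitionThermo(dG0=RT_283 * math.log(3), dV0=0.0)])
        assert populations(m, 0.0) == pytest.approx([0.75, 0.25])

    def test_extreme_energies_saturate_exactly(self):
        m = MultiStateModel(transitions=[TransitionThermo(dG0=5000.0, dV0=0.0)])
        assert populations(m, 0.0).tolist() == [1.0, 0.0]

    @settings(derandomize=True, max_examples=50)
    @given(dG0=st.floats(-20, 20), dV0=st.floats(-100, 100),
           dp=st.floats(0, 200))
    def test_normalization(self, dG0, dV0, dp):
        m = MultiStateModel(transitions=[TransitionThermo(dG0, dV0),
                                         TransitionThermo(-dG0 / 2, dV0 / 3)])
        p = populations(m, dp)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()

    def test_monotone_population_shift_for_linear_dG(self):
        m = MultiStateModel(transitions=[TransitionThermo(dG0=3.0, dV0=-40.0)])
        p2 = [populations(m, dp)[1] for dp in np.linspace(0, 200, 21)]
        assert all(b > a for a, b in zip(p2, p2[1:]))


class TestEnsembleShift:
    def _model(self, dG0=0.0, shifts=((7.0, 0, 0), (8.0, 0, 0))):
        return MultiStateModel(
            transitions=[TransitionThermo(dG0=dG0, dV0=0.0)],
            state_shifts={"HE1": [StateShift(*s) for s in shifts]})

    def test_equal_state_shifts_independent_of_dG(self):
        for dG0 in (-5, 0, 7):
            m = self._model(dG0, ((7.5, 0, 0), (7.5, 0, 0)))
            assert ensemble_shift(m, "HE1", 100.0) == pytest.approx(7.5)

    def test_midpoint_is_state_average(self):
        # tanh form: at dG = 0 the ensemble shift is (delta1 + delta2)/2
        assert ensemble_shift(self._model(), "HE1", 0.0) == pytest.approx(7.5)

    def test_unknown_atom(self):
        with pytest.raises(hp.UsageError):
            ensemble_shift(self._model(), "HB2", 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(dG0=st.floats(-10, 10), dV0=st.floats(-80, 80),
           d1=st.floats(6, 9), d2=st.floats(6, 9),
           b1=st.floats(-0.3, 0.3), b2=st.floats(-0.3, 0.3),
           dp=st.floats(0, 200))
    def test_identical_per_state_b_equals_shared_form(self, dG0, dV0, d1, d2,
                                                      b1, b2, dp):
        """With state-independent B coefficients the full per-state sum and
        the separated weighted-δ₀-plus-polynomial form agree exactly."""
        m = MultiStateModel(
            transitions=[TransitionThermo(dG0=dG0, dV0=dV0)],
            state_shifts={"a": [StateShift(d1, b1, b2), StateShift(d2, b1, b2)]})
        full = ensemble_shift(m, "a", dp, shared_compression=False)
        shared = ensemble_shift(m, "a", dp, shared_compression=True)
        assert full == pytest.approx(shared, abs=1e-12)


class TestCompressionCorrect:
    def test_zero_coefficients_identity(self):
        s = PressureSeries.from_arrays([1, 50, 100], [1.0, 1.1, 1.2])
        out = compression_correct(s, 0.0, 0.0)
        assert out.shifts.tolist() == s.shifts.tolist()

    def test_p0_point_unchanged(self):
        s = PressureSeries.from_arrays([0.1, 100], [2.0, 2.5])
        out = compression_correct(s, -0.5, 0.3)
        assert out.points[0].shift == 2.0

    def test_polynomial_corrected_by_its_fit_is_constant(self):
        s = gen_series(SimulationSpec(
            model="polynomial", params=dict(delta0=2.0, b1=-0.1, b2=0.05)))
        fit = fit_series(s)
        out = compression_correct(s, fit.b1, fit.b2)
        assert np.allclose(out.shifts, 2.0, atol=1e-10)

    def test_two_state_series_reduces_to_population_term(self):
        params = dict(dG0=3.0, dV0=-40.0, delta0_1=7.0, delta0_2=8.0,
                      b1=-0.1, b2=0.05)
        s = gen_series(SimulationSpec(model="two_state", params=params))
        out = compression_correct(s, -0.1, 0.05)
        m = MultiStateModel(
            transitions=[TransitionThermo(dG0=3.0, dV0=-40.0)],
            state_shifts={"a": [StateShift(7.0), StateShift(8.0)]})
        expected = [ensemble_shift(m, "a", p - 0.1) for p in out.pressures]
        assert np.allclose(out.shifts, expected, atol=1e-12)


class TestTwoStateFit:
    PARAMS = dict(dG0=4.0, dV0=-40.0, delta0_1=7.0, delta0_2=8.0,
                  b1=-0.1, b2=0.05)

    def test_noiseless_recovery(self):
        s = gen_series(SimulationSpec(model="two_state", params=self.PARAMS))
        fit = fit_two_state(s, (-0.1, 0.05))
        assert fit.thermo.dG0 == pytest.approx(4.0, rel=1e-6)
        assert fit.thermo.dV0 == pytest.approx(-40.0, rel=1e-6)
        assert fit.state1.delta0 == pytest.approx(7.0, rel=1e-6)
        assert fit.state2.delta0 == pytest.approx(8.0, rel=1e-6)

    def test_flat_series_not_identifiable(self):
        s = PressureSeries.from_arrays(np.linspace(1, 200, 8), [7.0] * 8)
        with pytest.raises(hp.NonIdentifiableError):
            fit_two_state(s, (0.0, 0.0))

    def test_too_few_points(self):
        s = PressureSeries.from_arrays([1, 50, 100, 150, 200],
                                       [7.0, 7.1, 7.3, 7.5, 7.6])
        with pytest.raises(hp.FitError):
            fit_two_state(s, (0.0, 0.0))

    def test_population_change_diagnostic_consistent(self):
        """The reported population change must match the fitted model's own
        populations at the range ends, and the warning flag must mirror the
        5-percentage-point rule."""
        params = dict(dG0=12.0, dV0=-10.0, delta0_1=7.0, delta0_2=11.0,
                      b1=0.0, b2=0.0)
        s = gen_series(SimulationSpec(model="two_state", params=params,
                                      noise_sd=0.0005, seed=3))
        fit = fit_two_state(s, (0.0, 0.0))
        m = MultiStateModel(transitions=[fit.thermo])
        p_lo = populations(m, float(s.pressures.min() - 0.1))[1]
        p_hi = populations(m, float(s.pressures.max() - 0.1))[1]
        assert fit.population_change == pytest.approx(abs(p_hi - p_lo))
        assert fit.identifiability_warning == (fit.population_change < 0.05)

    def test_deterministic_given_seed(self):
        s = gen_series(SimulationSpec(model="two_state", params=self.PARAMS,
                                      noise_sd=0.002, seed=11))
        f1 = fit_two_state(s, (-0.1, 0.05), seed=20200622)
        f2 = fit_two_state(s, (-0.1, 0.05), seed=20200622)
        assert f1.thermo == f2.thermo

    def test_saturating_regime_fits_opposite_sign_curvature(self):
        """A traversed two-state transition with linear ΔG yields a
        saturation-like polynomial: B2 opposes B1."""
        for dG0, dV0 in [(3.0, -40.0), (2.0, -40.0), (1.0, -20.0)]:
            params = dict(dG0=dG0, dV0=dV0, delta0_1=7.0, delta0_2=8.0,
                          b1=0.0, b2=0.0)
            s = gen_series(SimulationSpec(
                model="two_state", params=params,
                pressures=tuple(np.linspace(1, 200, 21))))
            fit = fit_series(s)
            assert np.sign(fit.b1) != np.sign(fit.b2)


class TestCompressibilityRatio:
    def test_simple_arithmetic(self):
        assert compressibility_ratio(-0.10, 0.05).ratio == pytest.approx(-0.5)

    def test_ala_hbeta_record(self, db):
        rec = db.lookup("Ala", "QB")
        res = compressibility_ratio(rec.b1, rec.b2)
        assert res.ratio == pytest.approx(-0.91, abs=0.005)
        assert "ΔG" in res.caveat or "valid" in res.caveat

    def test_undefined_for_zero_b1(self):
        with pytest.raises(hp.RatioUndefinedError):
            compressibility_ratio(0.0, 0.1)

    def test_small_dG_regime_matches_closed_form(self):
        """In |ΔG/2RT| << 1 the fitted B2/B1 approaches -(1/2)Δβ'/ΔV."""
        dV, dVdP = -2.0, 4.0  # Δβ' = -dVdP = -4 mL/mol/GPa
        params = dict(dG0=0.0, dV0=dV, dVdP=dVdP, delta0_1=7.0,
                      delta0_2=8.0, b1=0.0, b2=0.0)
        s = gen_series(SimulationSpec(
            model="two_state", params=params,
            pressures=tuple(np.linspace(1, 200, 21))))
        fit = fit_series(s)
        expected = 0.5 * dVdP / dV  # == -(1/2) * (-dVdP) / dV
        assert fit.b2 / fit.b1 == pytest.approx(expected, rel=0.1)
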