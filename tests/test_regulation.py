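"""State switching, the batch acetate-switch model and its staged
calibration."""

import numpy as np
import pandas as pd
import pytest

from dfba3d.fixtures import default_batch_params, synthetic_batch_data
from dfba3d.lattice import CELL
from dfba3d.regulation import (BatchCalibrationData, BatchModelParams,
                               CalibrationError, SwitchingModel, Transition,
                               calibrate_switching, default_switching_model,
                               regulation_step, simulate_batch,
                               switching_rate)

from conftest import closed_cell_lattice


def two_state_lattice(k12=0.0, k21=0.0, rho1=0.3, rho2=0.3):
    """Closed all-cell lattice with two states and constant switching
    rates (encoded through the alpha_0 coefficient)."""
    lat = closed_cell_lattice(n=3, states=("s1", "s2"))
    lat.rho[0][:] = rho1
    lat.rho[1][:] = rho2
    model = SwitchingModel({
        ("s1", "s2"): Transition(("tracer", "tracer"),
                                 (k12, 0, 0, 0, 0, 0)),
        ("s2", "s1"): Transition(("tracer", "tracer"),
                                 (k21, 0, 0, 0, 0, 0)),
    })
    return lat, model


class TestSwitchingRate:
    def test_zero_coefficients(self):
        tr = SwitchingModel({("a", "b"): Transition(("glucose", "acetate"),
                                                    (0,) * 6)})
        assert switching_rate(tr, ("a", "b"), 0.01, 0.01) == 0.0

    def test_negative_polynomial_clamped(self):
        tr = SwitchingModel({("a", "b"): Transition(("glucose", "acetate"),
                                                    (-1, 0, 0, 0, 0, 0))})
        assert switching_rate(tr, ("a", "b"), 1.0, 1.0) == 0.0

    def test_polynomial_arithmetic(self):
        tr = SwitchingModel({("a", "b"): Transition(
            ("glucose", "acetate"), (0.0, 2.0, 0.0, 100.0, 0.0, 0.0))})
        # 2 * 0.003 + 100 * 9e-6 = 6.9e-3
        assert switching_rate(tr, ("a", "b"), 0.003, 0.42) == pytest.approx(
            6.9e-3)

    def test_unknown_transition_rejected(self):
        with pytest.raises(KeyError):
            switching_rate(default_switching_model(), ("x", "y"), 0, 0)

    def test_continuity_near_clamp(self):
        tr = SwitchingModel({("a", "b"): Transition(
            ("glucose", "acetate"), (-1e-4, 1.0, 0, 0, 0, 0))})
        phis = np.linspace(0.0, 2.5e-4, 200)
        rates = [switching_rate(tr, ("a", "b"), p, 0.0) for p in phis]
        assert all(r >= 0 for r in rates)
        assert np.max(np.abs(np.diff(rates))) < 2e-5  # no jumps


class TestRegulationStep:
    def test_zero_rates_identity(self):
        lat, model = two_state_lattice(0.0, 0.0)
        before = lat.rho.copy()
        regulation_step(lat, model, 60.0)
        np.testing.assert_array_equal(lat.rho, before)

    def test_symmetric_rates_fixed_point(self):
        lat, model = two_state_lattice(1e-4, 1e-4, rho1=0.3, rho2=0.3)
        before = lat.rho.copy()
        regulation_step(lat, model, 60.0)
        np.testing.assert_allclose(lat.rho, before, rtol=1e-14)

    def test_euler_arithmetic(self):
        lat, model = two_state_lattice(1e-4, 0.0, rho1=0.6, rho2=0.0)
        regulation_step(lat, model, 60.0)
        assert lat.rho[0, 1, 1, 1] == pytest.approx(0.5964)
        assert lat.rho[1, 1, 1, 1] == pytest.approx(0.0036)

    def test_total_density_conserved_under_overdraw(self):
        # rate so large the naive Euler step would overdraw the donor
        lat, model = two_state_lattice(1.0, 0.0, rho1=0.5, rho2=0.1)
        with pytest.warns(RuntimeWarning):
            regulation_step(lat, model, 60.0)
        assert lat.rho[0].min() >= 0.0
        np.testing.assert_allclose(lat.total_rho(), 0.6, rtol=1e-14)


class TestSimulateBatch:
    def test_glucose_only_exponential(self):
        p = default_batch_params()
        df = simulate_batch(p, (0.01, 0.0, 0.05, 0.0), 4.0)
        # while glucose lasts, biomass is exponential at g_glc
        m = df["M_glc"].to_numpy()
        t = df["t"].to_numpy()
        fit = np.polyfit(t, np.log(m), 1)[0]
        assert fit == pytest.approx(p.g_glc, rel=1e-3)
        assert (np.diff(df["glc"]) <= 1e-15).all()

    def test_acetate_only_exponential(self):
        p = default_batch_params()
        df = simulate_batch(p, (0.0, 0.01, 0.0, 0.05), 4.0)
        fit = np.polyfit(df["t"], np.log(df["M_ace"]), 1)[0]
        assert fit == pytest.approx(p.g_ace, rel=1e-3)

    def test_diauxic_shape(self):
        p = default_batch_params()
        df = simulate_batch(p, (0.01, 0.0, 5e-3, 2e-3), 14.0)
        glc = df["glc"].to_numpy()
        ace = df["ace"].to_numpy()
        m_ace = df["M_ace"].to_numpy()
        t_exhaust = df["t"][glc < 1e-5].iloc[0]
        after = df["t"] > t_exhaust + 0.5
        # acetate consumers rise after glucose exhaustion...
        assert m_ace[after.to_numpy()].max() > 10 * m_ace[0] + 1e-6
        # ...and the accumulated acetate is eventually drawn down
        assert ace[-1] < ace[glc < 1e-5][0]
        # concentrations never negative
        assert (df[["glc", "ace"]] >= 0).all().all()

    def test_rejects_bad_inputs(self):
        p = default_batch_params()
        with pytest.raises(ValueError):
            simulate_batch(p, (-0.01, 0, 0.01, 0), 1.0)


class TestCalibration:
    def test_noiseless_round_trip(self):
        truth = default_batch_params()
        data = synthetic_batch_data(truth, noise_cv=0.0)
        fit = calibrate_switching(data)
        assert fit.g_glc == pytest.approx(truth.g_glc, rel=0.01)
        assert fit.g_ace == pytest.approx(truth.g_ace, rel=0.01)
        assert fit.v_glc == pytest.approx(truth.v_glc, rel=0.01)
        assert fit.v_ace == pytest.approx(truth.v_ace, rel=0.01)
        assert fit.eps_ace == pytest.approx(truth.eps_ace, rel=0.01)
        for key, tr in truth.switching.transitions.items():
            got = fit.switching.transitions[key].alpha
            for a_true, a_fit, free in zip(tr.alpha, got, tr.free):
                if free and a_true != 0:
                    assert a_fit == pytest.approx(a_true, rel=0.01)

    def test_noisy_growth_rate_recovery(self):
        truth = default_batch_params()
        errs_g, errs_a = [], []
        for rep in range(20):
            data = synthetic_batch_data(truth, noise_cv=0.05, seed=100 + rep)
            fit = calibrate_switching(data, stages=2)
            errs_g.append(abs(fit.g_glc - truth.g_glc) / truth.g_glc)
            errs_a.append(abs(fit.g_ace - truth.g_ace) / truth.g_ace)
        assert np.median(errs_g) < 0.05
        assert np.median(errs_a) < 0.05

    def test_missing_mixed_culture_reported(self):
        data = synthetic_batch_data(noise_cv=0.0)
        data.mixed = None
        with pytest.raises(CalibrationError, match="stage 3"):
            calibrate_switching(data)

    def test_missing_single_substrate_reported(self):
        data = synthetic_batch_data(noise_cv=0.0)
        data.acetate_only = None
        with pytest.raises(CalibrationError, match="stage 1"):
            calibrate_switching(data)
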