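"""The two-time-scale driver: steady-state cycles, forward projection,
colony summaries and the radial-expansion fit."""

import numpy as np
import pytest

from dfba3d.driver import (ColonySummary, fit_radial_rate,
                           project_consumption, run_colony_simulation,
                           steady_state_cycle, summarize)
from dfba3d.fixtures import toy_states
from dfba3d.lattice import (CELL, LatticeConfig, build_lattice,
                            default_substrates, seed_colony)
from dfba3d.metabolism import build_flux_table
from dfba3d.regulation import SwitchingModel, Transition


def open_lattice(dims=(10, 10, 10), agar=3, seed_rho=None, dtau=2e-3):
    cfg = LatticeConfig(dims=dims, lam=1e-5, agar_height=agar * 1e-5,
                        dtau=dtau, t_ss=0.5, t_grow=60.0)
    lat = build_lattice(cfg, default_substrates(), state_ids=("open",))
    if seed_rho:
        seed_colony(lat, "open", seed_rho)
    return lat


class TestSteadyStateCycle:
    def test_substep_count_matches_headline_cadence(self, toy_table):
        # 1 s relaxation at 1 ms sub-steps = 1000 kernel applications
        lat = open_lattice(dims=(4, 4, 6), agar=2, dtau=1e-3)
        diag = steady_state_cycle(lat, toy_table, dtau=1e-3, t_ss=1.0)
        assert diag["substeps"] == 1000

    def test_no_cells_pure_diffusion(self, toy_table):
        lat = open_lattice()
        glc0 = 2.5 / 180.16
        diag = steady_state_cycle(lat, toy_table, t_ss=0.5)
        glc = lat.ext_field("glucose")
        agar = lat.site == 1
        # agar glucose holds at its boundary value; nothing grows
        np.testing.assert_allclose(glc[agar], glc0, rtol=1e-6)
        assert (lat.growth == 0).all()

    def test_seeded_site_consumes_and_grows(self, toy_table):
        lat = open_lattice(seed_rho=0.65)
        steady_state_cycle(lat, toy_table, t_ss=1.0)
        i, j, k = lat.seed_site
        assert lat.growth[0, i, j, k] > 0
        # local oxygen and glucose drawn below their far-field values
        assert lat.ext_field("oxygen")[i, j, k] < 2.6e-4
        assert lat.ext_field("glucose")[i, j, k] < 2.5 / 180.16
        t = lat.tracked_names.index("oxygen")
        assert lat.vex[0, t, i, j, k] > 0

    def test_halving_t_ss_changes_little(self, toy_table):
        # time-scale separation: the window is long enough that halving it
        # moves the recorded steady-state fields by < 0.1%
        base = open_lattice(seed_rho=0.65)
        for _ in range(3):   # develop a small colony first
            steady_state_cycle(base, toy_table, t_ss=1.0)
        a = base.copy()
        b = base.copy()
        steady_state_cycle(a, toy_table, t_ss=1.0)
        steady_state_cycle(b, toy_table, t_ss=0.5)
        for i in range(a.ext.shape[0]):
            scale = np.abs(a.ext[i]).max()
            if scale == 0:
                continue
            assert np.abs(a.ext[i] - b.ext[i]).max() / scale < 1e-3

    def test_bit_identical_repeats(self, toy_table):
        runs = []
        for _ in range(2):
            lat = open_lattice(seed_rho=0.3)
            steady_state_cycle(lat, toy_table, t_ss=0.5)
            runs.append(lat)
        np.testing.assert_array_equal(runs[0].ext, runs[1].ext)
        np.testing.assert_array_equal(runs[0].vex, runs[1].vex)


class TestProjectConsumption:
    def test_zero_drift_no_change(self, small_lattice):
        small_lattice.drift = np.zeros_like(small_lattice.ext)
        before = small_lattice.ext.copy()
        project_consumption(small_lattice, t_grow=60.0, t_ss=1.0)
        np.testing.assert_array_equal(small_lattice.ext, before)

    def test_linear_drawdown(self, small_lattice):
        lat = small_lattice
        i = lat.sub_index("glucose")
        lat.drift = np.zeros_like(lat.ext)
        # constant drawdown at an interior agar site
        lat.drift[i, 4, 4, 1] = -1e-5
        before = lat.ext[i, 4, 4, 1]
        project_consumption(lat, t_grow=60.0, t_ss=1.0)
        assert lat.ext[i, 4, 4, 1] == pytest.approx(before - 59 * 1e-5)

    def test_overshoot_floored_at_zero(self, small_lattice):
        lat = small_lattice
        i = lat.sub_index("glucose")
        lat.drift = np.zeros_like(lat.ext)
        lat.drift[i, 4, 4, 1] = -1.0   # would go far below zero
        project_consumption(lat, t_grow=60.0, t_ss=1.0)
        assert lat.ext[i, 4, 4, 1] == 0.0


class TestSummarize:
    def test_empty_colony_all_zero(self, small_lattice):
        s = summarize(small_lattice)
        assert s.radius_m == 0 and s.height_m == 0 and s.biomass_g == 0

    def test_single_site_colony_conventions(self, small_lattice):
        lat = seed_colony(small_lattice, "cells", 0.5)
        s = summarize(lat)
        assert s.radius_m == 0.0
        assert s.height_m == pytest.approx(lat.config.lam)
        # biomass = rho * lam^3 * m_cell/V_cell
        assert s.biomass_g == pytest.approx(0.5 * 1e-15 * 2.58e5 * 1e3 / 1e3)

    def test_biomass_weighted_flux_averages(self, small_lattice):
        lat = small_lattice
        k = lat.n_agar_layers
        lat.site[2:6, 4, k] = CELL
        lat.rho[0, 2:6, 4, k] = 0.4
        lat.vex = np.zeros((1, 3) + lat.config.dims)
        lat.tracked_names = ("glucose", "oxygen", "acetate")
        t = 2  # acetate
        lat.vex[0, t, 2:4, 4, k] = -2.0   # half the biomass produces 2.0
        lat.vex[0, t, 4:6, 4, k] = 1.0    # the other half consumes 1.0
        s = summarize(lat)
        assert s.production["acetate"] == pytest.approx(1.0)
        assert s.uptake["acetate"] == pytest.approx(0.5)

    def test_o2_penetration_from_exponential_profile(self):
        cfg = LatticeConfig(dims=(31, 31, 8), lam=1e-5, agar_height=3e-5,
                            dtau=1e-3, t_ss=0.05, t_grow=60.0)
        lat = build_lattice(cfg, default_substrates(), state_ids=("cells",))
        k = lat.n_agar_layers
        lat.seed_site = (15, 15, k)
        lat.site[:, :, k] = CELL
        lat.rho[0, :, :, k] = 0.6
        o2 = lat.ext_field("oxygen")
        nx, ny = cfg.dims[0], cfg.dims[1]
        for i in range(nx):
            for j in range(ny):
                depth_m = min(i, nx - 1 - i, j, ny - 1 - j) * cfg.lam
                o2[i, j, k] = 2.6e-4 * np.exp(-depth_m / 20e-6)
        s = summarize(lat)
        # analytic 1% depth: 20 um * ln(100) = 92.1 um, resolved to one site
        assert s.o2_penetration_m == pytest.approx(92.1e-6, abs=cfg.lam)


class TestFitRadialRate:
    @staticmethod
    def series(times_hr, radii_um):
        return [ColonySummary(time_hr=t, radius_m=r * 1e-6, height_m=0.0,
                              biomass_g=0.0)
                for t, r in zip(times_hr, radii_um)]

    def test_exact_linear_slope_recovered(self):
        t = np.linspace(0, 24, 120)
        r = 5.0 + 0.011 * t * 3600
        fit = fit_radial_rate(self.series(t, r), window=(10, 24))
        assert fit.rate_um_per_s == pytest.approx(0.011, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_radius_zero_slope(self):
        t = np.linspace(0, 24, 60)
        fit = fit_radial_rate(self.series(t, np.full_like(t, 80.0)),
                              window=(5, 24))
        assert fit.rate_um_per_s == pytest.approx(0.0, abs=1e-12)

    def test_exponential_to_linear_transition_detected(self):
        t = np.linspace(0, 30, 301)
        g = 0.25  # hr^-1
        r0 = 5.0
        brk = 15.0
        r = np.where(t < brk, r0 * np.exp(g * t),
                     r0 * np.exp(g * brk) * (1 + g * (t - brk)))
        fit = fit_radial_rate(self.series(t, r), window=(20, 30))
        assert abs(fit.transition_time_hr - brk) <= 1.0

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 24, 60)
        with pytest.raises(ValueError):
            fit_radial_rate(self.series(t, t), window=(23.5, 24))


class TestRegulationReduction:
    def test_zero_switching_equals_no_regulation(self, toy_table_regulated):
        """With all switching rates zero the regulated machinery reduces to
        the plain two-state run bit for bit."""
        zero_sw = SwitchingModel({
            ("glc", "ace"): Transition(("glucose", "acetate"), (0.0,) * 6),
            ("ace", "glc"): Transition(("glucose", "acetate"), (0.0,) * 6),
        })

        def run(switching):
            cfg = LatticeConfig(dims=(10, 10, 10), lam=1e-5,
                                agar_height=3e-5, dtau=2e-3, t_ss=0.5,
                                t_grow=60.0)
            lat = build_lattice(cfg, default_substrates(),
                                state_ids=("glc", "ace"))
            seed_colony(lat, "glc", 0.5)
            lat, summaries = run_colony_simulation(
                lat, toy_table_regulated, switching=switching, hours=0.05)
            return lat, summaries

        a_lat, a_sum = run(zero_sw)
        b_lat, b_sum = run(None)
        np.testing.assert_array_equal(a_lat.rho, b_lat.rho)
        np.testing.assert_array_equal(a_lat.ext, b_lat.ext)
        assert [s.biomass_g for s in a_sum] == [s.biomass_g for s in b_sum]
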