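"""FBA layer: LP solutions against an independent linear-programming
oracle, availability constraints, exchange application, lookup tables and
the fermentation screen."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from dfba3d.fixtures import (CROWDING_BINDING, CROWDING_LIGHT, TOY_CAPS,
                             build_toy_model, toy_states)
from dfba3d.lattice import seed_colony
from dfba3d.metabolism import (CellState, FluxSolution, MetabolicModel,
                               apply_exchange_fluxes, build_flux_table,
                               exchange_constraints, fermentation_screen,
                               load_flux_table, query_flux_table,
                               save_flux_table, solve_fba)

OPEN = CellState("open")


def oracle_growth(c_glc, c_o2, c_ace, crowding=None):
    """Optimal toy-model growth rate by direct linear programming on the
    hand-reduced pathway variables (respiration r, overflow o, acetate
    oxidation a):

        max (6r + o + 2a)/65
        s.t. r + o <= c_glc; 3r + 2a <= c_o2; a - 2o <= c_ace; r,o,a >= 0
             (+ crowding: a_R r + a_O o + a_A a <= 1)

    Solved with scipy's HiGHS — fully independent of the cobra/GLPK path.
    """
    A = [[1, 1, 0], [3, 0, 2], [0, -2, 1]]
    b = [c_glc, c_o2, c_ace]
    if crowding:
        A.append([crowding["RESP"], crowding["OVF"], crowding["ACOX"]])
        b.append(1.0)
    res = linprog(c=[-6 / 65, -1 / 65, -2 / 65], A_ub=A, b_ub=b,
                  bounds=[(0, None)] * 3, method="highs")
    assert res.success
    return -res.fun


class TestSolveFBA:
    def test_aerobic_growth_no_secretion(self, toy_model):
        sol = solve_fba(toy_model, OPEN,
                        {"glucose": 10.4, "oxygen": 31.8, "acetate": 16.0})
        assert sol.g == pytest.approx(oracle_growth(10.4, 31.8, 16.0))
        assert sol.v_exchange["acetate"] >= -1e-9  # nothing secreted

    def test_anaerobic_overflow(self, toy_model):
        sol = solve_fba(toy_model, OPEN,
                        {"glucose": 10.4, "oxygen": 0.0, "acetate": 16.0})
        assert sol.g == pytest.approx(oracle_growth(10.4, 0.0, 16.0))
        assert sol.g > 0
        assert sol.v_exchange["acetate"] < -1e-6   # overflow secretion

    def test_nothing_to_eat(self, toy_model):
        sol = solve_fba(toy_model, OPEN,
                        {"glucose": 0.0, "oxygen": 0.0, "acetate": 0.0})
        assert sol.g == 0.0

    def test_aerobic_faster_than_anaerobic_and_acetate_growth(self, toy_model):
        g_aer = solve_fba(toy_model, OPEN, {"glucose": 10.4, "oxygen": 31.8,
                                            "acetate": 0.0}).g
        g_ana = solve_fba(toy_model, OPEN, {"glucose": 10.4, "oxygen": 0.0,
                                            "acetate": 0.0}).g
        g_ace = solve_fba(toy_model, OPEN, {"glucose": 0.0, "oxygen": 31.8,
                                            "acetate": 16.0}).g
        g_ace_anox = solve_fba(toy_model, OPEN, {"glucose": 0.0, "oxygen": 0.0,
                                                 "acetate": 16.0}).g
        assert g_aer > g_ace > g_ana > 0
        assert g_ace_anox == 0.0   # acetate growth requires oxygen

    @pytest.mark.parametrize("cvec", list(itertools.product(
        [0.0, 5.2, 10.4], [0.0, 15.9, 31.8], [0.0, 16.0])))
    def test_growth_matches_lp_oracle_on_grid(self, toy_model, cvec):
        sol = solve_fba(toy_model, OPEN, dict(zip(
            ("glucose", "oxygen", "acetate"), cvec)))
        assert sol.g == pytest.approx(
            oracle_growth(*cvec), abs=1e-9)

    def test_state_overrides_tighten(self, toy_model):
        glc_state, ace_state = toy_states("regulated")
        c = {"glucose": 10.4, "oxygen": 31.8, "acetate": 16.0}
        s_glc = solve_fba(toy_model, glc_state, c)
        assert s_glc.v_exchange["acetate"] <= 0  # may secrete, not consume
        s_ace = solve_fba(toy_model, ace_state, c)
        assert s_ace.v_exchange["glucose"] == pytest.approx(0.0, abs=1e-9)
        assert s_ace.g == pytest.approx(oracle_growth(0.0, 31.8, 16.0))

    def test_tie_break_determinism(self, toy_model):
        c = {"glucose": 10.4, "oxygen": 12.0, "acetate": 4.0}
        sols = [solve_fba(toy_model, OPEN, c) for _ in range(3)]
        for s in sols[1:]:
            assert s.g == sols[0].g
            assert s.v_exchange == sols[0].v_exchange

    def test_growth_monotone_in_constraints(self, toy_model):
        gs = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            gs.append(solve_fba(toy_model, OPEN,
                                {"glucose": 10.4 * f, "oxygen": 31.8 * f,
                                 "acetate": 16.0 * f}).g)
        assert all(b >= a - 1e-12 for a, b in zip(gs, gs[1:]))


class TestCrowding:
    def test_binding_budget_causes_aerobic_overflow(self, toy_model_crowded):
        sol = solve_fba(toy_model_crowded, OPEN,
                        {"glucose": 10.4, "oxygen": 31.8, "acetate": 16.0},
                        crowding=True)
        assert sol.g == pytest.approx(
            oracle_growth(10.4, 31.8, 16.0, CROWDING_BINDING))
        assert sol.v_exchange["acetate"] < -1e-6   # overflow despite oxygen
        # crowding slows the fastest growth
        free = solve_fba(toy_model_crowded, OPEN,
                         {"glucose": 10.4, "oxygen": 31.8, "acetate": 16.0})
        assert sol.g < free.g

    def test_light_budget_does_not_bind(self):
        model = build_toy_model(crowding=True, coefficients=CROWDING_LIGHT)
        sol = solve_fba(model, OPEN,
                        {"glucose": 10.4, "oxygen": 31.8, "acetate": 16.0},
                        crowding=True)
        assert sol.g == pytest.approx(oracle_growth(10.4, 31.8, 16.0))
        assert sol.v_exchange["acetate"] >= -1e-9  # no secretion

    def test_crowded_cells_prefer_glucose(self, toy_model_crowded):
        # at the binding budget no simultaneous glucose+acetate consumption
        sol = solve_fba(toy_model_crowded, OPEN,
                        {"glucose": 10.4, "oxygen": 31.8, "acetate": 16.0},
                        crowding=True)
        assert sol.v_exchange["glucose"] > 0
        assert sol.v_exchange["acetate"] <= 1e-9


class TestExchangeCoupling:
    def test_constraint_values(self, seeded_lattice, toy_model):
        lat = seeded_lattice
        i, j, k = lat.seed_site
        lat.ext[lat.sub_index("oxygen"), i, j, k] = 2.6e-4
        c = exchange_constraints(lat, (i, j, k), toy_model, dtau=1e-3)
        # passive O2 at 2.6e-4 M: raw 3628 mmol/gDwt/hr, capped at 31.8
        assert c["oxygen"] == pytest.approx(31.8)
        # no intracellular glucose yet
        assert c["glucose"] == 0.0

    def test_active_constraint_arithmetic(self, seeded_lattice, toy_model):
        lat = seeded_lattice
        i, j, k = lat.seed_site
        lat.rho[0, i, j, k] = 0.65
        lat.intra_field("glucose")[i, j, k] = 1e-6
        c = exchange_constraints(lat, (i, j, k), toy_model, dtau=1e-3)
        # (1e-6/0.65) * V/(m dtau) = 21.5 mmol/gDwt/hr, capped at 10.4
        raw = 1e-6 / 0.65 * 1e-15 / (2.58e-13 * 1e-3) * 3.6e6
        assert raw == pytest.approx(21.5, rel=1e-2)
        assert c["glucose"] == pytest.approx(10.4)

    def test_zero_flux_keeps_fields(self, seeded_lattice, toy_model):
        lat = seeded_lattice
        before = lat.ext.copy()
        sol = FluxSolution(0.5, {"glucose": 0.0, "oxygen": 0.0,
                                 "acetate": 0.0})
        apply_exchange_fluxes(lat, lat.seed_site, sol, toy_model, 1e-3)
        np.testing.assert_array_equal(lat.ext, before)
        i, j, k = lat.seed_site
        assert lat.growth[0, i, j, k] == 0.5

    def test_secretion_concentration_arithmetic(self, seeded_lattice,
                                                toy_model):
        lat = seeded_lattice
        i, j, k = lat.seed_site
        lat.rho[0, i, j, k] = 0.65
        sol = FluxSolution(0.0, {"glucose": 0.0, "oxygen": 0.0,
                                 "acetate": -3.5})
        apply_exchange_fluxes(lat, (i, j, k), sol, toy_model, 1e-3)
        # 3.5e-3 mol/g/hr * 258 g/l * (1e-3/3600) hr * 0.65 = 1.63e-7 M
        assert lat.ext_field("acetate")[i, j, k] == pytest.approx(1.6302e-7,
                                                                  rel=1e-3)

    def test_uptake_at_availability_empties_pool(self, seeded_lattice,
                                                 toy_model):
        lat = seeded_lattice
        i, j, k = lat.seed_site
        lat.rho[0, i, j, k] = 0.4
        o2i = lat.sub_index("oxygen")
        lat.ext[o2i, i, j, k] = 1e-9
        c = exchange_constraints(lat, (i, j, k), toy_model, dtau=1e-3)
        # consuming exactly the availability cancels the pool to zero
        sol = FluxSolution(0.0, {"glucose": 0.0, "oxygen": c["oxygen"] / 0.4,
                                 "acetate": 0.0})
        lat.rho[0, i, j, k] = 0.4
        apply_exchange_fluxes(lat, (i, j, k), sol, toy_model, 1e-3)
        assert lat.ext[o2i, i, j, k] == pytest.approx(0.0, abs=1e-18)

    def test_overdraw_aborts(self, seeded_lattice, toy_model):
        lat = seeded_lattice
        lat.rho[0][lat.seed_site] = 0.65
        sol = FluxSolution(0.0, {"glucose": 0.0, "oxygen": 31.8,
                                 "acetate": 0.0})
        lat.ext[lat.sub_index("oxygen")][lat.seed_site] = 1e-12
        with pytest.raises(FloatingPointError):
            apply_exchange_fluxes(lat, lat.seed_site, sol, toy_model, 1e-3)


class TestFluxTable:
    def test_nodes_match_direct_solves(self, toy_model, toy_table):
        names = toy_table.tracked
        rng = np.random.default_rng(3)
        picks = rng.integers(0, 5, size=(8, 3))
        picks[0] = (0, 0, 0)
        picks[1] = (4, 4, 4)
        for idx in picks:
            cvec = {n: float(toy_table.axes[a][idx[a]])
                    for a, n in enumerate(names)}
            direct = solve_fba(toy_model, OPEN, cvec)
            via = query_flux_table(toy_table, "open", cvec)
            assert via.g == pytest.approx(direct.g, abs=1e-9)
            for n in names:
                assert via.v_exchange[n] == pytest.approx(
                    direct.v_exchange[n], abs=1e-8)

    def test_zero_node_zero_growth(self, toy_table_regulated):
        for sid in toy_table_regulated.state_ids:
            assert toy_table_regulated.g[sid][0, 0, 0] == 0.0

    def test_midpoint_is_mean_of_nodes(self, toy_table):
        ax = toy_table.axes
        c_lo = {"glucose": ax[0][1], "oxygen": ax[1][2], "acetate": ax[2][1]}
        c_hi = dict(c_lo, glucose=ax[0][2])
        c_mid = dict(c_lo, glucose=0.5 * (ax[0][1] + ax[0][2]))
        g_lo = query_flux_table(toy_table, "open", c_lo).g
        g_hi = query_flux_table(toy_table, "open", c_hi).g
        g_mid = query_flux_table(toy_table, "open", c_mid).g
        assert g_mid == pytest.approx(0.5 * (g_lo + g_hi), rel=1e-12)

    def test_refinement_halves_interpolation_error(self, toy_model):
        coarse = build_flux_table(toy_model, [OPEN], n_nodes=5)
        fine = build_flux_table(toy_model, [OPEN], n_nodes=9)
        rng = np.random.default_rng(11)
        errs = {id(coarse): 0.0, id(fine): 0.0}
        for _ in range(100):
            cvec = {"glucose": rng.uniform(0, 10.4),
                    "oxygen": rng.uniform(0, 31.8),
                    "acetate": rng.uniform(0, 16.0)}
            direct = solve_fba(toy_model, OPEN, cvec).g
            for tab in (coarse, fine):
                err = abs(query_flux_table(tab, "open", cvec).g - direct)
                errs[id(tab)] = max(errs[id(tab)], err)
        assert errs[id(fine)] <= 0.5 * errs[id(coarse)] + 1e-12

    def test_out_of_range_clamped_and_uptake_capped(self, toy_table):
        sol = query_flux_table(toy_table, "open",
                               {"glucose": 99.0, "oxygen": 99.0,
                                "acetate": 99.0})
        assert sol.v_exchange["glucose"] <= 10.4 + 1e-9
        lo = query_flux_table(toy_table, "open",
                              {"glucose": 0.3, "oxygen": 31.8,
                               "acetate": 0.0})
        assert lo.v_exchange["glucose"] <= 0.3 + 1e-12

    def test_roundtrip_persistence(self, tmp_path, toy_table):
        p = tmp_path / "table.h5"
        save_flux_table(toy_table, str(p))
        back = load_flux_table(str(p))
        assert back.tracked == toy_table.tracked
        assert back.model_checksum == toy_table.model_checksum
        for sid in toy_table.state_ids:
            np.testing.assert_array_equal(back.g[sid], toy_table.g[sid])
            np.testing.assert_array_equal(back.vex[sid], toy_table.vex[sid])


class TestFermentationScreen:
    def test_toy_anaerobic_sole_product(self, toy_model):
        ranked = fermentation_screen(toy_model, aerobic=False)
        assert list(ranked.index) == ["EX_ace"]
        assert ranked.iloc[0] == pytest.approx(20.8)

    def test_starved_screen_empty(self, toy_model):
        ranked = fermentation_screen(toy_model, aerobic=False, glucose=0.0)
        assert ranked.empty


class TestSBMLRoundTrip:
    def test_toy_model_survives_sbml(self, toy_model, tmp_path):
        p = tmp_path / "toy.xml"
        toy_model.to_sbml(str(p))
        back = MetabolicModel.from_sbml(
            str(p), tracked=dict(toy_model.tracked), caps=dict(TOY_CAPS))
        sol = solve_fba(back, OPEN,
                        {"glucose": 10.4, "oxygen": 31.8, "acetate": 16.0})
        assert sol.g == pytest.approx(oracle_growth(10.4, 31.8, 16.0))
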