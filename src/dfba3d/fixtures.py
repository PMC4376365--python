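"""Self-contained test inputs: a desk-scale toy metabolic model, synthetic
batch-calibration data, and an analytic reaction-diffusion column scenario.

Everything here is generated programmatically from seeds and parameters —
no data files.  The toy model reproduces, at desk scale, the three
metabolic behaviours the colony simulations rely on: fast aerobic growth on
glucose (respiration), slower anaerobic growth with acetate overflow, and
intermediate aerobic growth on acetate.  Its yields are tuned so the fully
constrained aerobic doubling time is ~43 min, the regime of fast-growing
E. coli on glucose minimal medium.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lattice import (CELL, Lattice, LatticeConfig, SubstrateSpec,
                      build_lattice)
from .metabolism import CellState, FluxTable, MetabolicModel
from .regulation import (BatchCalibrationData, BatchModelParams,
                         SwitchingModel, default_switching_model,
                         simulate_batch)

#: kinetic uptake caps shared with the headline parameter set,
#: mmol gDwt^-1 hr^-1
TOY_CAPS = {"glucose": 10.4, "oxygen": 31.8, "acetate": 16.0}

#: crowding coefficients (gDwt hr mmol^-1) under which the fastest aerobic
#: solution mixes respiration with acetate overflow (the budget binds)
CROWDING_BINDING = {"RESP": 0.12, "OVF": 0.01, "ACOX": 0.05}
#: coefficients under which the budget never binds at the kinetic caps:
#: pure respiration remains optimal and no acetate is secreted
CROWDING_LIGHT = {"RESP": 0.05, "OVF": 0.01, "ACOX": 0.05}


def build_toy_model(crowding: bool = False,
                    coefficients: Optional[dict[str, float]] = None,
                    ) -> MetabolicModel:
    """Small stoichiometric model with the colony-relevant phenotypes.

    Reactions (X is a lumped biomass precursor):

    * ``RESP``  glc + 3 O2 -> 6 X + 2 CO2   (high-yield respiration)
    * ``OVF``   glc -> 2 ace + 1 X          (low-yield overflow)
    * ``ACOX``  ace + 2 O2 -> 2 X + 2 CO2   (acetate oxidation)
    * ``BIOMASS`` 65 X -> growth            (objective, flux in hr^-1)

    plus exchanges for glucose/oxygen/acetate (uptake bounded by the kinetic
    caps) and CO2 (secretion only).  With ``crowding`` the model carries the
    given coefficients (default: the binding set).
    """
    from cobra import Metabolite, Model, Reaction

    m = Model("toy_colony")
    glc = Metabolite("glc_c", name="glucose", compartment="c")
    o2 = Metabolite("o2_c", name="oxygen", compartment="c")
    ace = Metabolite("ace_c", name="acetate", compartment="c")
    co2 = Metabolite("co2_c", name="CO2", compartment="c")
    x = Metabolite("precursor_c", name="biomass precursor", compartment="c")

    def rxn(rid, mets, lb, ub):
        r = Reaction(rid)
        r.add_metabolites(mets)
        r.lower_bound, r.upper_bound = lb, ub
        return r

    m.add_reactions([
        rxn("EX_glc", {glc: -1}, -TOY_CAPS["glucose"], 0.0),
        rxn("EX_o2", {o2: -1}, -TOY_CAPS["oxygen"], 0.0),
        rxn("EX_ace", {ace: -1}, -TOY_CAPS["acetate"], 1000.0),
        rxn("EX_co2", {co2: -1}, 0.0, 1000.0),
        rxn("RESP", {glc: -1, o2: -3, x: 6, co2: 2}, 0.0, 1000.0),
        rxn("OVF", {glc: -1, ace: 2, x: 1}, 0.0, 1000.0),
        rxn("ACOX", {ace: -1, o2: -2, x: 2, co2: 2}, 0.0, 1000.0),
        rxn("BIOMASS", {x: -65}, 0.0, 1000.0),
    ])
    m.objective = "BIOMASS"
    m.solver = "glpk"
    coeffs = None
    if crowding:
        coeffs = dict(coefficients) if coefficients else dict(CROWDING_BINDING)
    return MetabolicModel(
        cobra_model=m, biomass_id="BIOMASS",
        tracked={"glucose": "EX_glc", "oxygen": "EX_o2", "acetate": "EX_ace"},
        caps=dict(TOY_CAPS), crowding=coeffs, name="toy_colony")


def toy_states(variant: str = "regulated") -> list[CellState]:
    """Cell states for the colony variants.

    * ``unregulated``: one unconstrained state free to co-consume.
    * ``regulated``: a glucose-consuming state (acetate uptake capped at 0)
      and an acetate-consuming state (glucose uptake capped at 0).
    * ``non-crossfeeding``: the glucose-consuming state alone — the colony
      can secrete but never consume acetate.
    """
    glc_state = CellState("glc", {"acetate": 0.0})
    ace_state = CellState("ace", {"glucose": 0.0})
    if variant == "unregulated":
        return [CellState("open")]
    if variant == "regulated":
        return [glc_state, ace_state]
    if variant == "non-crossfeeding":
        return [glc_state]
    raise ValueError(f"unknown variant {variant!r}")


def default_batch_params() -> BatchModelParams:
    """Batch model parameters used to generate synthetic calibration data:
    glucose growth at 0.75 hr^-1 and acetate growth at 0.28 hr^-1 (doubling
    ~55 min and ~2.5 h), consumption rates matching the uptake caps scaled
    to concentration units, and the default switching structure."""
    return BatchModelParams(
        g_glc=0.75, g_ace=0.28,
        v_glc=10.4e-3,   # mol (gDwt l^-1)^-1 hr^-1
        v_ace=8.0e-3,
        eps_ace=4.0e-3,
        switching=default_switching_model())


def synthetic_batch_data(params: Optional[BatchModelParams] = None,
                         noise_cv: float = 0.0,
                         seed: int = 0,
                         n_points: int = 25) -> BatchCalibrationData:
    """Batch-culture time series for the three calibration conditions, with
    optional multiplicative log-normal noise of coefficient of variation
    ``noise_cv``.  The same seed always yields the same dataset.

    Conditions: glucose-only (8 h, inoculum 0.01 gDwt l^-1 in glucose-state,
    13.9 mM glucose), acetate-only (10 h, acetate-state inoculum, 10 mM
    acetate), and a mixed diauxic culture (12 h, glucose-state inoculum,
    5 mM glucose + 2 mM acetate).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if params is None:
        params = default_batch_params()
    rng = np.random.default_rng(seed)

    def run(y0, hours, n=None):
        t = np.linspace(0.0, hours, n or n_points)
        df = simulate_batch(params, y0, hours, t_eval=t)
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv ** 2))
            for col in ("M_glc", "M_ace", "glc", "ace"):
                fac = np.exp(rng.normal(-sigma ** 2 / 2, sigma, len(df)))
                df[col] = df[col] * fac
            df["M"] = df["M_glc"] + df["M_ace"]
        return df

    return BatchCalibrationData(
        glucose_only=run((0.01, 0.0, 1.39e-2, 0.0), 8.0),
        acetate_only=run((0.0, 0.01, 0.0, 1.0e-2), 10.0),
        # two-state inoculum and 3-min sampling: the switching transients
        # (minutes) must be resolved for the rates to be identifiable
        mixed=run((0.008, 0.004, 5.0e-3, 2.0e-3), 12.0,
                  n=max(n_points, 241)))


def constant_consumption_table(v_uptake: float, cap: float,
                               n_nodes: int = 2) -> FluxTable:
    """A synthetic single-state flux table whose oxygen uptake is constant
    (``v_uptake`` mmol gDwt^-1 hr^-1) at every node — a zero-order sink.
    Queries clamp uptake to availability, so consumption shuts off smoothly
    as the pool empties.  Glucose/acetate axes are singleton zeros."""
    axes = (np.array([0.0]),
            np.linspace(0.0, cap, max(n_nodes, 2)),
            np.array([0.0]))
    shape = tuple(len(a) for a in axes)
    vex = np.zeros((3,) + shape)
    vex[1] = v_uptake
    return FluxTable(
        tracked=("glucose", "oxygen", "acetate"), axes=axes,
        state_ids=("sink",), g={"sink": np.zeros(shape)},
        vex={"sink": vex}, feasible={"sink": np.ones(shape, dtype=bool)},
        caps={"glucose": 0.0, "oxygen": cap, "acetate": 0.0},
        model_checksum="synthetic-constant-sink")


def analytic_column_scenario(q_vol: float = 1.48e-3,
                             c0: float = 2.6e-4,
                             rho: float = 0.65,
                             n_sites: int = 40,
                             lam: float = 1.0e-5,
                             dtau: float = 1.0e-3,
                             m_cell: float = 2.58e-13,
                             v_cell: float = 1.0e-18):
    """A 1 x 1 x N column of cell sites under an air source, consuming a
    substrate at constant volumetric rate ``q_vol`` (M s^-1) — the classic
    zero-order-consumption oxygen microprofile.

    Returns ``(lattice, table, analytic)`` where ``analytic(z)`` is the
    closed-form steady profile:

        C(z) = C0 (1 - z/z_p)^2  for z <= z_p,   z_p = sqrt(2 D_eff C0 / q)

    and 0 beyond the penetration depth z_p.  Depth is measured downward
    from the clamped air source node (``analytic.depths`` gives the depth of
    each cell site's centre, top first).  The table is the constant-sink
    pseudo-table matching ``q_vol`` at volume fraction ``rho``.
    """
    d_aq = 2.6e-9
    spec = [
        SubstrateSpec("glucose", d_aq=7.8e-10, d_agar=7.4e-10,
                      transport="active", hindered=True,
                      uptake_vmax=10.4, uptake_km=3.7e-4),
        SubstrateSpec("oxygen", d_aq=d_aq, d_agar=2.5e-9, air_value=c0),
        SubstrateSpec("acetate", d_aq=1.2e-9, d_agar=1.1e-9, hindered=True),
    ]
    # column: 1 agar layer at the bottom, n_sites cells, air at the top
    cfg = LatticeConfig(dims=(1, 1, n_sites + 2), lam=lam,
                        agar_height=lam, dtau=dtau,
                        m_cell=m_cell, v_cell=v_cell)
    lat = build_lattice(cfg, spec, state_ids=("sink",))
    lat.site[0, 0, 1:n_sites + 1] = CELL
    lat.rho[0, 0, 0, 1:n_sites + 1] = rho
    lat.seed_site = (0, 0, 1)

    # specific uptake rate reproducing q_vol at this volume fraction
    from . import units
    v_uptake = q_vol / (rho * units.specific_to_volumetric(1.0, m_cell, v_cell))
    table = constant_consumption_table(v_uptake, cap=max(2 * v_uptake, 1.0))

    d_eff = d_aq  # oxygen is not hindered
    z_p = float(np.sqrt(2.0 * d_eff * c0 / q_vol))

    def analytic(z):
        z = np.asarray(z, dtype=float)
        prof = c0 * np.maximum(1.0 - z / z_p, 0.0) ** 2
        return prof

    analytic.z_p = z_p
    # depth of each cell site centre below the air source node
    analytic.depths = (n_sites + 1 - np.arange(1, n_sites + 1)) * lam
    analytic.cell_ks = np.arange(1, n_sites + 1)
    return lat, table, analytic
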