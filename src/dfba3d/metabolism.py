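"""Per-site flux balance analysis and the precomputed flux lookup table.

The metabolic layer answers one question for the spatial simulation: given
how much of each tracked substrate the cells in a site may take up during a
sub-step (the availability constraint vector, mmol gDwt^-1 hr^-1), how fast
do they grow and what do they exchange with their surroundings?  The answer
is a linear program — maximize the biomass objective subject to steady-state
stoichiometry and bounds — solved either directly (through cobrapy/GLPK) or,
for the inner simulation loop, via a precomputed lookup table queried by
multilinear interpolation.

Alternate optima are resolved parsimoniously: after fixing the optimal
growth rate, total absolute flux is minimized, which makes the reported
exchange fluxes unique and the tables reproducible.

Sign convention: the spatial layer speaks uptake-positive; conversion to the
model's exchange convention (uptake = negative exchange flux) happens only
at the LP boundary.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels, units
from .lattice import ACTIVE, CELL, Lattice

_ZERO_TOL = 1e-9


@dataclass
class MetabolicModel:
    """A stoichiometric model plus the bookkeeping the spatial layer needs.

    ``tracked`` maps each spatially tracked substrate name to its exchange
    reaction id; ``caps`` holds the kinetic maximum uptake rate per tracked
    substrate (mmol gDwt^-1 hr^-1) — the upper end of every lookup-table
    axis.  ``crowding`` optionally assigns per-reaction crowding
    coefficients a_r (gDwt hr mmol^-1) charging each unit of absolute flux
    against a unit intracellular volume budget.
    """

    cobra_model: object
    biomass_id: str
    tracked: dict[str, str]
    caps: dict[str, float]
    crowding: Optional[dict[str, float]] = None
    name: str = "model"

    def __post_init__(self) -> None:
        rxns = {r.id for r in self.cobra_model.reactions}
        if self.biomass_id not in rxns:
            raise ValueError(f"biomass reaction {self.biomass_id!r} not in model")
        for sub, ex in self.tracked.items():
            if ex not in rxns:
                raise ValueError(f"exchange {ex!r} for {sub!r} not in model")
            if sub not in self.caps:
                raise ValueError(f"no kinetic cap for tracked substrate {sub!r}")

    @property
    def tracked_names(self) -> tuple[str, ...]:
        return tuple(self.tracked)

    def checksum(self) -> str:
        h = hashlib.sha1()
        for r in sorted(self.cobra_model.reactions, key=lambda r: r.id):
            h.update(r.id.encode())
            h.update(np.array([r.lower_bound, r.upper_bound]).tobytes())
            for m, c in sorted(r.metabolites.items(), key=lambda t: t[0].id):
                h.update(m.id.encode())
                h.update(np.float64(c).tobytes())
        h.update(self.biomass_id.encode())
        if self.crowding:
            for rid, a in sorted(self.crowding.items()):
                h.update(rid.encode())
                h.update(np.float64(a).tobytes())
        return h.hexdigest()

    @classmethod
    def from_sbml(cls, path: str, tracked: dict[str, str],
                  caps: dict[str, float], biomass_id: Optional[str] = None,
                  crowding: Optional[dict[str, float]] = None,
                  name: Optional[str] = None) -> "MetabolicModel":
        from cobra.io import read_sbml_model
        m = read_sbml_model(path)
        if biomass_id is None:
            objs = [r.id for r in m.reactions
                    if r.objective_coefficient not in (0, 0.0)]
            if len(objs) != 1:
                raise ValueError("cannot auto-detect the biomass objective")
            biomass_id = objs[0]
        return cls(m, biomass_id, dict(tracked), dict(caps), crowding,
                   name or m.id or "model")

    def to_sbml(self, path: str) -> None:
        from cobra.io import write_sbml_model
        write_sbml_model(self.cobra_model, path)


@dataclass(frozen=True)
class CellState:
    """A regulatory state: per-substrate uptake caps that tighten the model.

    ``uptake_caps`` maps tracked substrate names to an upper bound imposed on
    that substrate's uptake (e.g. 0.0 on acetate for the glucose-consuming
    state).  Overrides may only tighten the model's own bounds.
    """

    id: str
    uptake_caps: Mapping[str, float] = field(default_factory=dict)

    def cap_for(self, substrate: str, default: float) -> float:
        return min(default, self.uptake_caps.get(substrate, default))


@dataclass
class FluxSolution:
    """Growth rate (hr^-1) and tracked exchange fluxes (mmol gDwt^-1 hr^-1,
    uptake positive)."""

    g: float
    v_exchange: dict[str, float]
    feasible: bool = True

    def vector(self, tracked: Sequence[str]) -> np.ndarray:
        return np.array([self.v_exchange[t] for t in tracked])


def read_crowding_csv(path: str) -> dict[str, float]:
    """Crowding coefficients from a two-column CSV (reaction id, a_r)."""
    df = pd.read_csv(path, header=None, names=["reaction", "a"],
                     comment="#", skipinitialspace=True)
    if (df["a"].astype(float) < 0).any():
        raise ValueError("crowding coefficients must be non-negative")
    return dict(zip(df["reaction"].astype(str), df["a"].astype(float)))


def _add_crowding_constraint(m, coefficients: Mapping[str, float]):
    expr = None
    for rid, a in coefficients.items():
        if a == 0.0:
            continue
        r = m.reactions.get_by_id(rid)
        term = a * (r.forward_variable + r.reverse_variable)
        expr = term if expr is None else expr + term
    if expr is None:
        return None
    cons = m.problem.Constraint(expr, ub=1.0, name="molecular_crowding")
    m.add_cons_vars(cons)
    return cons


def solve_fba(model: MetabolicModel, state: CellState,
              constraints: Mapping[str, float],
              crowding: bool = False) -> FluxSolution:
    """Solve the per-site LP: maximize biomass subject to the model bounds
    tightened by the state's overrides and the availability constraints, then
    break ties by minimizing total absolute flux at the optimal growth.

    With ``crowding`` the additional linear budget sum_r a_r |v_r| <= 1 is
    imposed (flux splitting via the solver's forward/reverse variables).
    Infeasible programs yield a zero, infeasible-flagged solution.
    """
    from cobra.flux_analysis import pfba

    if crowding and not model.crowding:
        raise ValueError("model carries no crowding coefficients")
    names = model.tracked_names
    for n in names:
        if constraints.get(n, 0.0) < 0:
            raise ValueError("availability constraints must be non-negative")
    m = model.cobra_model
    with m:
        for n in names:
            rxn = m.reactions.get_by_id(model.tracked[n])
            cap = model.caps[n]
            avail = min(constraints.get(n, cap), cap)
            rxn.lower_bound = -state.cap_for(n, avail)
        if crowding:
            _add_crowding_constraint(m, model.crowding)
        g = m.slim_optimize(error_value=np.nan)
        if not np.isfinite(g):
            return FluxSolution(0.0, {n: 0.0 for n in names}, feasible=False)
        sol = pfba(m)
        g = float(sol.fluxes[model.biomass_id])
        vex = {n: -float(sol.fluxes[model.tracked[n]]) for n in names}
    return FluxSolution(max(g, 0.0), vex, feasible=True)


# --------------------------------------------------------------------------
# coupling to the lattice fields (Eq.-level operations, one site at a time)
# --------------------------------------------------------------------------

def exchange_constraints(lattice: Lattice, site: tuple[int, int, int],
                         model: MetabolicModel, dtau: float) -> dict[str, float]:
    """Availability constraint vector for one cell site: the specific uptake
    rate (mmol gDwt^-1 hr^-1) that would exhaust the local pool in one
    sub-step — phi * V_cell/(m_cell dtau) for passive substrates, the
    intracellular pool over the total volume fraction for active ones — each
    capped at the substrate's kinetic maximum."""
    i, j, k = site
    if lattice.site[i, j, k] != CELL:
        raise ValueError("constraints are defined for cell sites only")
    rho_tot = float(lattice.rho[:, i, j, k].sum())
    if rho_tot <= 0.0:
        return {}
    cfg = lattice.config
    fac = units.availability_factor(cfg.m_cell, cfg.v_cell, dtau)
    out = {}
    for name in model.tracked_names:
        spec = lattice.substrates[lattice.sub_index(name)]
        if spec.transport == ACTIVE:
            avail = lattice.intra_field(name)[i, j, k] / rho_tot * fac
        else:
            avail = lattice.ext_field(name)[i, j, k] * fac
        out[name] = float(np.clip(avail, 0.0, model.caps[name]))
    return out


def apply_exchange_fluxes(lattice: Lattice, site: tuple[int, int, int],
                          solution: FluxSolution, model: MetabolicModel,
                          dtau: float, state_id: Optional[str] = None) -> Lattice:
    """Apply one state's exchange fluxes at one site:
    phi <- phi - v * (m_cell dtau / V_cell) * rho_state.  Uptake of actively
    imported substrates is drawn from the intracellular pool; secretion
    (v < 0) always goes to the shared extracellular field.  A pool driven
    below -1e-15 M signals a constraint/solution mismatch and aborts."""
    i, j, k = site
    cfg = lattice.config
    si = 0 if state_id is None else lattice.state_index(state_id)
    rho_s = float(lattice.rho[si, i, j, k])
    fac = units.flux_to_concentration_factor(cfg.m_cell, cfg.v_cell, dtau)
    for name, v in solution.v_exchange.items():
        spec = lattice.substrates[lattice.sub_index(name)]
        dphi = v * fac * rho_s
        if v > 0 and spec.transport == ACTIVE:
            pool = lattice.intra_field(name)
        else:
            pool = lattice.ext_field(name)
        pool[i, j, k] -= dphi
        if pool[i, j, k] < -1e-15:
            raise FloatingPointError(
                f"{name} pool driven to {pool[i, j, k]:g} M at {site}")
        pool[i, j, k] = max(pool[i, j, k], 0.0)
    lattice.growth[si, i, j, k] = solution.g
    return lattice


# --------------------------------------------------------------------------
# flux lookup table
# --------------------------------------------------------------------------

@dataclass
class FluxTable:
    """Precomputed FBA solutions on a rectangular grid of availability
    constraint vectors, one block per cell state."""

    tracked: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    state_ids: tuple[str, ...]
    g: dict[str, np.ndarray]            # state -> grid of growth rates
    vex: dict[str, np.ndarray]          # state -> (n_tracked, *grid)
    feasible: dict[str, np.ndarray]     # state -> boolean grid
    caps: dict[str, float]
    model_checksum: str = ""

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.axes)

    def packed(self, state_order: Sequence[str] | None = None):
        """(gtab, vtab) arrays stacked over states, for the numba kernel."""
        order = tuple(state_order) if state_order else self.state_ids
        gtab = np.stack([self.g[s] for s in order])
        vtab = np.stack([self.vex[s] for s in order])
        return np.ascontiguousarray(gtab), np.ascontiguousarray(vtab)


def default_axes(model: MetabolicModel, n_nodes: int = 17) -> tuple[np.ndarray, ...]:
    """Linear grids from 0 to each tracked substrate's kinetic cap."""
    return tuple(np.linspace(0.0, model.caps[n], n_nodes)
                 for n in model.tracked_names)


def build_flux_table(model: MetabolicModel, states: Sequence[CellState],
                     axes: Sequence[np.ndarray] | None = None,
                     n_nodes: int = 17, crowding: bool = False,
                     progress: bool = False) -> FluxTable:
    """Exhaustively solve the LP at every grid node for every state.

    Node infeasibilities are recorded, not fatal.  Axes must be strictly
    increasing and span [0, cap] for each tracked substrate.
    """
    names = model.tracked_names
    if axes is None:
        axes = default_axes(model, n_nodes)
    axes = tuple(np.asarray(a, dtype=float) for a in axes)
    if len(axes) != len(names):
        raise ValueError("one axis per tracked substrate required")
    for name, ax in zip(names, axes):
        if ax.ndim != 1 or len(ax) < 1 or np.any(np.diff(ax) <= 0):
            raise ValueError(f"axis for {name} must be strictly increasing")
        if ax[0] != 0.0 or not np.isclose(ax[-1], model.caps[name]):
            raise ValueError(f"axis for {name} must span [0, cap]")
    shape = tuple(len(a) for a in axes)
    g = {s.id: np.zeros(shape) for s in states}
    vex = {s.id: np.zeros((len(names),) + shape) for s in states}
    feas = {s.id: np.ones(shape, dtype=bool) for s in states}
    for state in states:
        for idx in itertools.product(*(range(n) for n in shape)):
            cvec = {n: axes[a][idx[a]] for a, n in enumerate(names)}
            sol = solve_fba(model, state, cvec, crowding=crowding)
            g[state.id][idx] = sol.g
            feas[state.id][idx] = sol.feasible
            for a, n in enumerate(names):
                vex[state.id][(a,) + idx] = sol.v_exchange[n]
    return FluxTable(tracked=names, axes=axes,
                     state_ids=tuple(s.id for s in states), g=g, vex=vex,
                     feasible=feas, caps=dict(model.caps),
                     model_checksum=model.checksum())


def query_flux_table(table: FluxTable, state: str | CellState,
                     constraints) -> FluxSolution:
    """Multilinear interpolation of growth and exchange fluxes at an
    arbitrary constraint vector (clamped to [0, cap] per component); each
    interpolated uptake is additionally clamped to the queried constraint so
    cells never consume more than is available."""
    sid = state.id if isinstance(state, CellState) else state
    if isinstance(constraints, Mapping):
        cvec = np.array([constraints[n] for n in table.tracked], dtype=float)
    else:
        cvec = np.asarray(constraints, dtype=float)
    nd = len(table.axes)
    locs = []
    for a in range(nd):
        ax = table.axes[a]
        x = float(np.clip(cvec[a], ax[0], ax[-1]))
        idx, frac = _kernels._locate(ax, x)
        locs.append((idx, frac))
    g_val = 0.0
    v_val = np.zeros(nd)
    for corner in itertools.product((0, 1), repeat=nd):
        w = 1.0
        idx = []
        for a, c in enumerate(corner):
            i0, f = locs[a]
            n = len(table.axes[a])
            idx.append(min(i0 + c, n - 1))
            w *= f if c else (1.0 - f)
        if w == 0.0:
            continue
        idx = tuple(idx)
        g_val += w * table.g[sid][idx]
        v_val += w * table.vex[sid][(slice(None),) + idx]
    v_val = np.minimum(v_val, np.maximum(cvec, 0.0))
    return FluxSolution(float(g_val),
                        {n: float(v_val[a]) for a, n in enumerate(table.tracked)},
                        feasible=True)


def save_flux_table(table: FluxTable, path: str) -> None:
    """Persist a table as HDF5: one group per state (g, vex, feasible
    datasets), axes and metadata at the root."""
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["tracked"] = list(table.tracked)
        f.attrs["state_ids"] = list(table.state_ids)
        f.attrs["model_checksum"] = table.model_checksum
        f.attrs["caps"] = [table.caps[n] for n in table.tracked]
        for a, n in enumerate(table.tracked):
            f.create_dataset(f"axes/{n}", data=table.axes[a])
        for sid in table.state_ids:
            grp = f.create_group(f"states/{sid}")
            grp.create_dataset("g", data=table.g[sid])
            grp.create_dataset("vex", data=table.vex[sid])
            grp.create_dataset("feasible", data=table.feasible[sid])


def load_flux_table(path: str) -> FluxTable:
    import h5py
    with h5py.File(path, "r") as f:
        tracked = tuple(str(t) for t in f.attrs["tracked"])
        state_ids = tuple(str(s) for s in f.attrs["state_ids"])
        caps = {n: float(c) for n, c in zip(tracked, f.attrs["caps"])}
        axes = tuple(f[f"axes/{n}"][...] for n in tracked)
        g = {s: f[f"states/{s}/g"][...] for s in state_ids}
        vex = {s: f[f"states/{s}/vex"][...] for s in state_ids}
        feas = {s: f[f"states/{s}/feasible"][...] for s in state_ids}
        return FluxTable(tracked=tracked, axes=axes, state_ids=state_ids,
                         g=g, vex=vex, feasible=feas, caps=caps,
                         model_checksum=str(f.attrs["model_checksum"]))


def fermentation_screen(model: MetabolicModel, aerobic: bool,
                        glucose: Optional[float] = None,
                        crowding: bool = False) -> pd.Series:
    """Rank fermentation/secretion products: solve with glucose at its cap
    (or the given rate), oxygen at its cap (aerobic) or 0 (anaerobic), and
    other tracked uptakes at 0, then report every non-zero secretion
    exchange flux sorted descending (mmol gDwt^-1 hr^-1)."""
    import logging

    from cobra.flux_analysis import pfba

    # cobra's boundary-type heuristic warns on single-compartment models
    logging.getLogger("cobra.medium.boundary_types").setLevel(logging.ERROR)
    names = model.tracked_names
    cvec = {n: 0.0 for n in names}
    if "glucose" in cvec:
        cvec["glucose"] = model.caps["glucose"] if glucose is None else glucose
    if "oxygen" in cvec:
        cvec["oxygen"] = model.caps["oxygen"] if aerobic else 0.0
    m = model.cobra_model
    with m:
        for n in names:
            rxn = m.reactions.get_by_id(model.tracked[n])
            rxn.lower_bound = -min(cvec[n], model.caps[n])
        if crowding:
            _add_crowding_constraint(m, model.crowding or {})
        g = m.slim_optimize(error_value=np.nan)
        if not np.isfinite(g) or g < _ZERO_TOL:
            return pd.Series(dtype=float)
        sol = pfba(m)
        secreted = {r.id: float(sol.fluxes[r.id]) for r in m.exchanges
                    if r.id != model.biomass_id
                    and sol.fluxes[r.id] > _ZERO_TOL}
    return pd.Series(secreted).sort_values(ascending=False)
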