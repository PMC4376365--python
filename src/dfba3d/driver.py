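"""Orchestration of the two-time-scale simulation loop and the colony
summary observables.

The loop exploits the separation between substrate diffusion (sub-second)
and colony growth (minutes): an inner steady-state cycle iterates
diffusion -> active uptake -> per-site FBA (via the lookup table) for a
relaxation window t_ss at sub-step dtau, after which the recorded growth
rates and exchange fluxes drive the outer colony cycle — exponential
growth, expansion relaxation, regulatory switching, and forward projection
of the converged consumption rates until the next colony update.

Everything is deterministic: no random numbers appear anywhere in the loop,
and all sweeps are Jacobi, so identical configurations give bit-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels, units
from .diffusion import apply_dirichlet, diffusivity_field, dirichlet_indices
from .growth import ExpansionReport, growth_step, relax_expansion
from .lattice import ACTIVE, AGAR, AIR, CELL, Lattice
from .metabolism import FluxTable
from .regulation import SwitchingModel, regulation_step
from .uptake import UptakeKinetics


@dataclass
class ColonySummary:
    """Macroscopic observables of one colony snapshot.

    Radius and height use the half-maximum volume-fraction contour
    (total rho >= rho_max / 2); colony-wide uptake/production rates are
    biomass-weighted means of the positive/negative parts of the recorded
    exchange fluxes; penetration depths are NaN while the corresponding
    gradient has not yet formed.
    """

    time_hr: float
    radius_m: float
    height_m: float
    biomass_g: float
    uptake: dict[str, float] = field(default_factory=dict)      # mmol/gDwt/hr
    production: dict[str, float] = field(default_factory=dict)
    state_volume: dict[str, float] = field(default_factory=dict)  # m^3
    o2_penetration_m: float = float("nan")
    glc_penetration_m: float = float("nan")

    def to_row(self) -> dict:
        row = {"time_hr": self.time_hr, "radius_m": self.radius_m,
               "height_m": self.height_m, "biomass_g": self.biomass_g,
               "o2_penetration_m": self.o2_penetration_m,
               "glc_penetration_m": self.glc_penetration_m}
        for n, v in self.uptake.items():
            row[f"uptake_{n}"] = v
        for n, v in self.production.items():
            row[f"production_{n}"] = v
        for n, v in self.state_volume.items():
            row[f"volume_{n}"] = v
        return row


def summaries_frame(summaries: Sequence[ColonySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def _colony_kmax(lattice: Lattice, margin: int = 4) -> int:
    """z-extent of the active region: everything above is undisturbed air."""
    nz = lattice.config.dims[2]
    occupied = np.flatnonzero(lattice.total_rho().any(axis=(0, 1)))
    top = int(occupied[-1]) if occupied.size else lattice.n_agar_layers
    return min(nz, top + 1 + margin)


def _table_meta(lattice: Lattice, table: FluxTable):
    """Index arrays wiring the table's tracked substrates to lattice fields."""
    tr_sub = np.empty(3, dtype=np.int64)
    tr_act = np.empty(3, dtype=np.int64)
    caps = np.empty(3)
    if len(table.tracked) != 3:
        raise ValueError("the driver kernel expects exactly 3 tracked substrates")
    for t, name in enumerate(table.tracked):
        tr_sub[t] = lattice.sub_index(name)
        spec = lattice.substrates[tr_sub[t]]
        tr_act[t] = (lattice.active_index(name)
                     if spec.transport == ACTIVE else -1)
        caps[t] = table.caps[name]
    return tr_sub, tr_act, caps


def steady_state_cycle(lattice: Lattice, table: FluxTable,
                       dtau: Optional[float] = None,
                       t_ss: Optional[float] = None,
                       kmax: Optional[int] = None) -> dict:
    """Relax the substrate fields to quasi-steady state.

    Runs t_ss/dtau sub-steps of diffusion -> Michaelis-Menten uptake ->
    table-FBA, records per-site growth rates and exchange fluxes from the
    final sub-step, measures the mean field drift over the last 5% of
    sub-steps (used by :func:`project_consumption`) and returns a
    diagnostics dict including the max relative field change over the last
    10% of sub-steps.
    """
    cfg = lattice.config
    dtau = cfg.dtau if dtau is None else dtau
    t_ss = cfg.t_ss if t_ss is None else t_ss
    nsub = max(1, int(round(t_ss / dtau)))
    if kmax is None:
        kmax = _colony_kmax(lattice)
    if tuple(table.state_ids) != tuple(lattice.state_ids):
        raise ValueError("table states do not match lattice states")
    lattice.tracked_names = tuple(table.tracked)

    nx, ny, nz = cfg.dims
    ns = len(lattice.state_ids)
    if lattice.vex is None or lattice.vex.shape[:2] != (ns, 3):
        lattice.vex = np.zeros((ns, 3, nx, ny, nz))
    rho_tot = lattice.total_rho()
    d_field = diffusivity_field(lattice)
    dirichlet = dirichlet_indices(lattice)
    tr_sub, tr_act, caps = _table_meta(lattice, table)
    gtab, vtab = table.packed(lattice.state_ids)
    ax0, ax1, ax2 = (np.ascontiguousarray(a, dtype=float) for a in table.axes)
    avail_fac = units.availability_factor(cfg.m_cell, cfg.v_cell, dtau)
    conc_fac = units.flux_to_concentration_factor(cfg.m_cell, cfg.v_cell, dtau)
    fac = dtau / cfg.lam ** 2
    active = [(lattice.sub_index(s.name), lattice.active_index(s.name),
               UptakeKinetics(s.uptake_vmax, s.uptake_km, cfg.m_cell,
                              cfg.v_cell).vmax_volumetric, s.uptake_km)
              for s in lattice.substrates if s.transport == ACTIVE]

    ext = lattice.ext
    scratch = ext.copy()
    air_values = [s.air_value for s in lattice.substrates]
    n_tail = max(1, int(round(0.05 * nsub)))
    conv_at = max(0, int(round(0.9 * nsub)) - 1)
    drift_at = nsub - n_tail - 1
    drift_snap = None
    conv_snap = None
    capped = 0
    for it in range(nsub):
        for i in range(len(lattice.substrates)):
            _kernels.diffuse_substrate(ext[i], scratch[i], lattice.site,
                                       d_field[i], air_values[i], fac, kmax)
        ext, scratch = scratch, ext
        lattice.ext = ext
        apply_dirichlet(lattice, dirichlet)
        for sub_i, act_i, vmax_vol, km in active:
            capped += _kernels.mm_uptake(ext[sub_i], lattice.intra[act_i],
                                         rho_tot, lattice.site, vmax_vol, km,
                                         dtau, kmax)
        bad = _kernels.fba_apply(lattice.site, lattice.rho, ext,
                                 lattice.intra, lattice.growth, lattice.vex,
                                 gtab, vtab, ax0, ax1, ax2, caps,
                                 tr_sub, tr_act, avail_fac, conc_fac, kmax)
        if bad:
            raise FloatingPointError(
                f"{bad} substrate pools driven negative during FBA update")
        if it % 25 == 24 or it == nsub - 1:
            lo = ext.min()
            if not np.isfinite(lo) or lo < -1e-15:
                raise FloatingPointError(
                    f"steady-state divergence: min field {lo:g} M")
        if it == conv_at and nsub > 1:
            conv_snap = ext.copy()
        if it == drift_at:
            drift_snap = ext.copy()

    if drift_snap is not None:
        lattice.drift = (ext - drift_snap) / (n_tail * dtau)
    else:
        lattice.drift = np.zeros_like(ext)
    convergence = float("nan")
    if conv_snap is not None:
        num = np.abs(ext - conv_snap).reshape(len(lattice.substrates), -1).max(1)
        den = np.abs(ext).reshape(len(lattice.substrates), -1).max(1) + 1e-300
        convergence = float((num / den).max())
    return {"substeps": nsub, "uptake_caps_hit": int(capped),
            "max_relative_change": convergence, "kmax": kmax}


def project_consumption(lattice: Lattice, t_grow: Optional[float] = None,
                        t_ss: Optional[float] = None,
                        include_production: bool = False) -> Lattice:
    """Extrapolate the converged net local consumption rates over the
    remainder of the colony interval (t_grow - t_ss), flooring fields at
    zero and re-imposing the boundary conditions.

    By default only depletion (negative drift — reservoir drawdown and
    nutrient exhaustion, the slow processes the quasi-steady windows cannot
    capture on their own) is projected.  Projecting the accumulation side as
    well (``include_production``) amplifies any not-yet-converged diffusion
    transient by t_grow/t_ss and can destabilize a long run; fields that
    build up (secreted acetate) instead converge to their quasi-steady
    plume through the relaxation windows themselves.
    """
    cfg = lattice.config
    t_grow = cfg.t_grow if t_grow is None else t_grow
    t_ss = cfg.t_ss if t_ss is None else t_ss
    horizon = max(0.0, t_grow - t_ss)
    if horizon == 0.0 or lattice.drift is None:
        return lattice
    for i, s in enumerate(lattice.substrates):
        f = lattice.ext[i]
        drift = lattice.drift[i]
        if not include_production:
            drift = np.minimum(drift, 0.0)
        new = f + drift * horizon
        # diffusive refilling can never push a field above its source value
        source = max(s.air_value, s.dirichlet_agar_boundary or 0.0)
        if source > 0.0:
            np.minimum(new, np.maximum(f, source), out=new)
        np.maximum(new, 0.0, out=new)
        lattice.ext[i] = new
    apply_dirichlet(lattice)
    air = lattice.site == AIR
    for i, s in enumerate(lattice.substrates):
        lattice.ext[i][air] = s.air_value
    return lattice


def colony_cycle(lattice: Lattice, table: FluxTable,
                 switching: Optional[SwitchingModel] = None,
                 t_grow: Optional[float] = None,
                 time_hr: float = 0.0,
                 kmax: Optional[int] = None,
                 ) -> tuple[Lattice, ColonySummary, ExpansionReport]:
    """One outer colony update: growth -> expansion -> regulation ->
    forward projection -> summary.  Requires a completed steady-state cycle
    (recorded growth rates and exchange fluxes)."""
    cfg = lattice.config
    t_grow = cfg.t_grow if t_grow is None else t_grow
    if kmax is None:
        kmax = _colony_kmax(lattice)
    growth_step(lattice, t_grow)
    lattice, report = relax_expansion(lattice, kmax=kmax)
    if switching is not None:
        regulation_step(lattice, switching, t_grow)
    project_consumption(lattice, t_grow)
    return lattice, summarize(lattice, time_hr), report


def summarize(lattice: Lattice, time_hr: float = 0.0) -> ColonySummary:
    """Macroscopic colony observables from the current fields."""
    cfg = lattice.config
    lam = cfg.lam
    rho_tot = lattice.total_rho()
    cell_mask = lattice.site == CELL
    total_rho_sum = float(rho_tot[cell_mask].sum()) if cell_mask.any() else 0.0
    summary = ColonySummary(time_hr=time_hr, radius_m=0.0, height_m=0.0,
                            biomass_g=0.0)
    if total_rho_sum == 0.0:
        summary.uptake = {s.name: 0.0 for s in lattice.substrates}
        summary.production = {s.name: 0.0 for s in lattice.substrates}
        summary.state_volume = {s: 0.0 for s in lattice.state_ids}
        return summary

    summary.biomass_g = total_rho_sum * lam ** 3 * \
        units.cell_density_g_per_l(cfg.m_cell, cfg.v_cell) * units.L_PER_M3
    summary.state_volume = {
        sid: float(lattice.rho[i].sum()) * lam ** 3
        for i, sid in enumerate(lattice.state_ids)}

    half = cfg.rho_max / 2.0
    dense = rho_tot >= half
    n_agar = lattice.n_agar_layers
    seed = lattice.seed_site or (cfg.dims[0] // 2, cfg.dims[1] // 2, n_agar)
    if dense.any():
        ii, jj, kk = np.nonzero(dense)
        summary.radius_m = float(
            np.sqrt((ii - seed[0]) ** 2 + (jj - seed[1]) ** 2).max()) * lam
        summary.height_m = float(kk.max() - n_agar + 1) * lam

    # biomass-weighted average uptake/production per substrate
    if lattice.vex is not None and lattice.tracked_names is not None:
        for t, name in enumerate(lattice.tracked_names):
            up = 0.0
            prod = 0.0
            for si in range(lattice.rho.shape[0]):
                v = lattice.vex[si, t][cell_mask]
                r = lattice.rho[si][cell_mask]
                up += float((np.maximum(v, 0.0) * r).sum())
                prod += float((np.maximum(-v, 0.0) * r).sum())
            summary.uptake[name] = up / total_rho_sum
            summary.production[name] = prod / total_rho_sum

    # oxygen penetration: first cell layer above the agar, marching inward
    # from the colony edge along the four cardinal rays through the seed
    try:
        o2 = lattice.ext_field("oxygen")
        spec = lattice.substrates[lattice.sub_index("oxygen")]
        thr = 0.01 * spec.air_value
        k0 = n_agar
        depths = []
        for axis, direction in ((0, 1), (0, -1), (1, 1), (1, -1)):
            if axis == 0:
                line_dense = dense[:, seed[1], k0]
                line_o2 = o2[:, seed[1], k0]
                start = seed[0]
            else:
                line_dense = dense[seed[0], :, k0]
                line_o2 = o2[seed[0], :, k0]
                start = seed[1]
            idxs = np.flatnonzero(line_dense)
            if idxs.size == 0:
                continue
            edge = idxs.max() if direction > 0 else idxs.min()
            pos = edge
            depth = None
            while (pos - start) * direction >= 0:
                if line_dense[pos] and line_o2[pos] < thr:
                    depth = abs(edge - pos) * lam
                    break
                pos -= direction
            if depth is not None:
                depths.append(depth)
        if depths:
            summary.o2_penetration_m = float(np.mean(depths))
    except KeyError:
        pass

    # glucose penetration: distance upward from the agar surface, at the
    # colony axis, to the first glucose-starved site
    try:
        glc = lattice.ext_field("glucose")
        spec = lattice.substrates[lattice.sub_index("glucose")]
        ref = spec.dirichlet_agar_boundary or 0.0
        if ref > 0:
            column = glc[seed[0], seed[1], n_agar:]
            col_cell = cell_mask[seed[0], seed[1], n_agar:]
            starved = np.flatnonzero(col_cell & (column < 0.01 * ref))
            if starved.size:
                summary.glc_penetration_m = float(starved[0] + 0.5) * lam
    except KeyError:
        pass
    return summary


@dataclass
class RadialFit:
    rate_um_per_s: float
    transition_time_hr: float
    r_squared: float


def fit_radial_rate(summaries: Sequence[ColonySummary] | pd.DataFrame,
                    window: tuple[float, float],
                    ic_margin: float = 0.0) -> RadialFit:
    """Least-squares slope of radius vs time over a late window (um s^-1)
    and the exponential-to-linear transition time.

    The transition time is found by a two-segment changepoint fit —
    exponential growth up to the breakpoint, linear expansion after — taking
    the breakpoint with the smallest total squared error; it is reported
    only when the broken model beats both single-regime fits by at least
    ``ic_margin`` on the Akaike information criterion (NaN otherwise).
    """
    df = summaries if isinstance(summaries, pd.DataFrame) \
        else summaries_frame(summaries)
    t_hr = df["time_hr"].to_numpy(dtype=float)
    r_um = df["radius_m"].to_numpy(dtype=float) * 1e6
    lo, hi = window
    w = (t_hr >= lo) & (t_hr <= hi)
    if w.sum() < 5:
        raise ValueError("need at least 5 summary points in the window")
    t_s = t_hr[w] * 3600.0
    slope, intercept = np.polyfit(t_s, r_um[w], 1)
    pred = slope * t_s + intercept
    ss_res = float(((r_um[w] - pred) ** 2).sum())
    ss_tot = float(((r_um[w] - r_um[w].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    def aic(sse, n, k):
        return n * np.log(max(sse, 1e-300) / n) + 2 * k

    def sse_lin(t, r):
        b, a = np.polyfit(t, r, 1)
        return float(((r - (b * t + a)) ** 2).sum())

    def sse_exp(t, r):
        b, a = np.polyfit(t, np.log(r), 1)
        return float(((r - np.exp(a + b * t)) ** 2).sum())

    transition = float("nan")
    pos = r_um > 0
    tp, rp = t_hr[pos], r_um[pos]
    n = len(tp)
    if n >= 8:
        best = (np.inf, float("nan"))
        for ci in range(3, n - 3):
            sse = sse_exp(tp[:ci + 1], rp[:ci + 1]) + \
                sse_lin(tp[ci:], rp[ci:])
            if sse < best[0]:
                best = (sse, float(tp[ci]))
        single = min(aic(sse_exp(tp, rp), n, 2), aic(sse_lin(tp, rp), n, 2))
        if aic(best[0], n, 5) + ic_margin < single:
            transition = best[1]
    return RadialFit(rate_um_per_s=float(slope),
                     transition_time_hr=transition, r_squared=r2)


def run_colony_simulation(lattice: Lattice, table: FluxTable,
                          switching: Optional[SwitchingModel] = None,
                          hours: float = 12.0,
                          dtau: Optional[float] = None,
                          t_ss: Optional[float] = None,
                          t_grow: Optional[float] = None,
                          checkpoint_cb: Optional[Callable] = None,
                          checkpoint_every: int = 60,
                          ) -> tuple[Lattice, list[ColonySummary]]:
    """Run the full two-time-scale loop for a simulated duration.

    Returns the final lattice and one :class:`ColonySummary` per colony
    cycle.  ``checkpoint_cb(cycle_index, lattice)`` is invoked every
    ``checkpoint_every`` cycles if given.
    """
    cfg = lattice.config
    t_grow = cfg.t_grow if t_grow is None else t_grow
    n_cycles = int(round(hours * 3600.0 / t_grow))
    summaries: list[ColonySummary] = []
    for cycle in range(n_cycles):
        kmax = _colony_kmax(lattice)
        steady_state_cycle(lattice, table, dtau=dtau, t_ss=t_ss, kmax=kmax)
        time_hr = (cycle + 1) * t_grow / 3600.0
        lattice, summary, _ = colony_cycle(lattice, table, switching,
                                           t_grow=t_grow, time_hr=time_hr,
                                           kmax=kmax)
        summaries.append(summary)
        if checkpoint_cb is not None and (cycle + 1) % checkpoint_every == 0:
            checkpoint_cb(cycle + 1, lattice)
    # leave the returned lattice on a converged steady-state window so the
    # substrate fields are consistent with the recorded exchange fluxes
    if n_cycles > 0:
        steady_state_cycle(lattice, table, dtau=dtau, t_ss=t_ss,
                           kmax=_colony_kmax(lattice))
    return lattice, summaries
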