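"""Substrate-dependent switching between regulatory states, and the batch
"acetate switch" model used to calibrate the switching rates.

Cells interconvert between states (here: glucose-consuming and
acetate-consuming) with first-order kinetics whose rates depend on up to two
local substrate concentrations through a clamped quadratic polynomial:

    k = max(0, a0 + a1*phi_m + a2*phi_n + a3*phi_m^2 + a4*phi_n^2
               + a5*phi_m*phi_n)

The coefficients are calibrated against batch-culture dynamics of a
two-population growth model (glucose consumers and acetate consumers
exchanging biomass through the same switching rates) by a staged fit:
single-substrate growth curves give the growth rates, the matching
concentration curves give the consumption/production rates, and the mixed
(diauxic) culture finally pins down the switching coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .lattice import CELL, Lattice

#: concentration scale (M) of the smooth gate that shuts growth and
#: consumption off as a substrate is exhausted (the "floor at zero" rule)
GATE_SCALE = 1e-6


class CalibrationError(RuntimeError):
    """A calibration stage is under-determined by the supplied data."""


@dataclass(frozen=True)
class Transition:
    """One ordered state transition i -> j and its rate polynomial.

    ``substrates`` names (phi_m, phi_n); ``alpha`` holds the six polynomial
    coefficients (units making the rate s^-1 with concentrations in M);
    ``free`` marks which coefficients a calibration may adjust.
    """

    substrates: tuple[str, str]
    alpha: tuple[float, float, float, float, float, float]
    free: tuple[bool, ...] = (False,) * 6

    def rate(self, phi_m: float, phi_n: float) -> float:
        a = self.alpha
        val = (a[0] + a[1] * phi_m + a[2] * phi_n + a[3] * phi_m ** 2
               + a[4] * phi_n ** 2 + a[5] * phi_m * phi_n)
        return max(0.0, val)


@dataclass(frozen=True)
class SwitchingModel:
    """Rate polynomials for every declared ordered state pair."""

    transitions: dict[tuple[str, str], Transition]

    def rate(self, transition: tuple[str, str], phi_m, phi_n) -> float:
        if transition not in self.transitions:
            raise KeyError(f"unknown transition {transition}")
        return self.transitions[transition].rate(phi_m, phi_n)

    def with_alphas(self, values: Mapping[tuple[str, str], Sequence[float]]
                    ) -> "SwitchingModel":
        out = dict(self.transitions)
        for key, alpha in values.items():
            out[key] = replace(out[key], alpha=tuple(alpha))
        return SwitchingModel(out)


def switching_rate(model: SwitchingModel, transition: tuple[str, str],
                   phi_m: float, phi_n: float) -> float:
    """Evaluate one transition's rate (s^-1) at local concentrations (M)."""
    if phi_m < 0 or phi_n < 0:
        raise ValueError("concentrations must be non-negative")
    return model.rate(transition, phi_m, phi_n)


def default_switching_model() -> SwitchingModel:
    """Glucose <-> acetate switching defaults.

    These coefficients are NOT literature values: they were calibrated once
    against this package's own synthetic batch-culture data (see
    ``fixtures.synthetic_batch_data``) and are shipped as a self-consistent
    default.  Supply your own coefficients to model a measured system.
    The structure encodes the acetate switch: leaving the glucose state
    requires acetate to be present and is suppressed while glucose remains
    above ~0.2 mM; the return to glucose consumption scales with the glucose
    concentration.
    """
    return SwitchingModel({
        ("glc", "ace"): Transition(
            substrates=("glucose", "acetate"),
            #            1    phi_glc  phi_ace  glc^2  ace^2  glc*ace
            alpha=(0.0, 0.0, 0.3, 0.0, 0.0, -1.5e3),
            free=(False, False, True, False, False, True)),
        ("ace", "glc"): Transition(
            substrates=("glucose", "acetate"),
            alpha=(0.0, 0.15, 0.0, 0.0, 0.0, 0.0),
            free=(False, True, False, False, False, False)),
    })


def regulation_step(lattice: Lattice, model: SwitchingModel,
                    t_grow: float) -> Lattice:
    """Explicit-Euler update of the state volume fractions at every cell
    site: rho_i <- rho_i + sum_j [k_{j->i} rho_j - k_{i->j} rho_i] * t_grow.

    Outflow from a state is summed over all declared transitions out of it;
    if the summed outflow would drive a state negative, its outflows are
    scaled back proportionally so that sum_i rho_i is conserved exactly.
    Emits a warning through the return value when any k * t_grow exceeds 1
    (explicit-Euler accuracy limit).
    """
    cell = lattice.site == CELL
    if not cell.any():
        return lattice
    conc = {}
    rates = {}
    warn = False
    for key, tr in model.transitions.items():
        for nm in tr.substrates:
            if nm not in conc:
                conc[nm] = lattice.ext_field(nm)[cell]
        phi_m = conc[tr.substrates[0]]
        phi_n = conc[tr.substrates[1]]
        a = tr.alpha
        k = np.maximum(0.0, a[0] + a[1] * phi_m + a[2] * phi_n
                       + a[3] * phi_m ** 2 + a[4] * phi_n ** 2
                       + a[5] * phi_m * phi_n)
        rates[key] = k
        if np.any(k * t_grow > 1.0):
            warn = True
    sids = lattice.state_ids
    rho_c = {s: lattice.rho[i][cell] for i, s in enumerate(sids)}
    # proportional scale-back of outflows that would overdraw a state
    outflow_k = {s: 0.0 for s in sids}
    for (src, dst), k in rates.items():
        outflow_k[src] = outflow_k[src] + k
    scale = {s: np.minimum(1.0, 1.0 / np.maximum(outflow_k[s] * t_grow, 1e-300))
             for s in sids}
    delta = {s: np.zeros_like(rho_c[s]) for s in sids}
    for (src, dst), k in rates.items():
        moved = k * t_grow * scale[src] * rho_c[src]
        delta[src] -= moved
        delta[dst] += moved
    for i, s in enumerate(sids):
        lattice.rho[i][cell] = rho_c[s] + delta[s]
    if warn:
        import warnings
        warnings.warn("switching rate * t_grow exceeded 1; explicit-Euler "
                      "regulation update may be inaccurate", RuntimeWarning)
    return lattice


# --------------------------------------------------------------------------
# batch acetate-switch model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BatchModelParams:
    """Parameters of the two-population batch model.

    Growth rates in hr^-1; ``v_glc``/``v_ace`` are substrate consumption
    rates and ``eps_ace`` the acetate production rate, all in
    mol (gDwt l^-1)^-1 hr^-1 so that concentrations are M when biomass is in
    gDwt l^-1.  ``switching`` supplies k_{glc->ace} and k_{ace->glc} (s^-1).
    """

    g_glc: float
    g_ace: float
    v_glc: float
    v_ace: float
    eps_ace: float
    switching: SwitchingModel

    def __post_init__(self) -> None:
        for n in ("g_glc", "g_ace", "v_glc", "v_ace", "eps_ace"):
            if getattr(self, n) < 0:
                raise ValueError(f"{n} must be non-negative")


@dataclass
class BatchCalibrationData:
    """Time series (hr) of biomass (gDwt l^-1) and concentrations (M) for a
    glucose-only, an acetate-only and a mixed culture.  Each frame has
    columns t, M, glc, ace (optionally M_glc, M_ace)."""

    glucose_only: Optional[pd.DataFrame] = None
    acetate_only: Optional[pd.DataFrame] = None
    mixed: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for nm in ("glucose_only", "acetate_only", "mixed"):
            df = getattr(self, nm)
            if df is None:
                continue
            if np.any(np.diff(df["t"].to_numpy()) <= 0):
                raise ValueError(f"{nm}: times must be strictly increasing")
            if (df[[c for c in ("M", "glc", "ace") if c in df]] < 0).any().any():
                raise ValueError(f"{nm}: values must be non-negative")


def _gate(phi: np.ndarray | float) -> np.ndarray | float:
    """Smooth floor: fraction of a rate that survives as phi -> 0."""
    p = np.maximum(phi, 0.0)
    return p / (p + GATE_SCALE)


def simulate_batch(params: BatchModelParams,
                   initial: Sequence[float],
                   duration: float,
                   t_eval: Optional[np.ndarray] = None,
                   step: float = 0.05) -> pd.DataFrame:
    """Integrate the four coupled batch equations.

    ``initial`` is (M_glc, M_ace, [glc], [ace]); ``duration`` in hours.
    Growth and consumption terms carry a smooth gate that vanishes with the
    substrate, flooring concentrations at zero.  Returns a frame with
    columns t, M_glc, M_ace, glc, ace, M.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if any(v < 0 for v in initial):
        raise ValueError("initial values must be non-negative")
    sw = params.switching

    def rhs(t, y):
        m_g, m_a, glc, ace = y
        gg = _gate(glc)
        ga = _gate(ace)
        k_ga = sw.rate(("glc", "ace"), glc, ace) * 3600.0  # s^-1 -> hr^-1
        k_ag = sw.rate(("ace", "glc"), glc, ace) * 3600.0
        dm_g = params.g_glc * m_g * gg + k_ag * m_a - k_ga * m_g
        dm_a = params.g_ace * m_a * ga + k_ga * m_g - k_ag * m_a
        dglc = -params.v_glc * m_g * gg
        dace = params.eps_ace * m_g * gg - params.v_ace * m_a * ga
        return [dm_g, dm_a, dglc, dace]

    if t_eval is None:
        t_eval = np.arange(0.0, duration + step / 2, step)
    sol = solve_ivp(rhs, (0.0, float(duration)), list(initial), t_eval=t_eval,
                    method="LSODA", rtol=1e-8, atol=1e-12, max_step=0.25)
    if not sol.success:
        raise RuntimeError(f"batch integration failed: {sol.message}")
    y = np.maximum(sol.y, 0.0)
    return pd.DataFrame({"t": sol.t, "M_glc": y[0], "M_ace": y[1],
                         "glc": y[2], "ace": y[3], "M": y[0] + y[1]})


def _fit_window(df: pd.DataFrame, substrate: str) -> np.ndarray:
    """Points usable for the exponential/consumption stages: substrate still
    above 5% of its initial value (and comfortably above the gate scale)."""
    phi = df[substrate].to_numpy()
    return (phi > 0.05 * phi[0]) & (phi > 20 * GATE_SCALE)


def calibrate_switching(data: BatchCalibrationData,
                        template: Optional[SwitchingModel] = None,
                        stages: int = 3) -> BatchModelParams:
    """Staged least-squares calibration of the batch model.

    Stage 1 fits g_glc and g_ace by log-linear regression of the
    single-substrate biomass curves; stage 2 fits v_glc, v_ace and eps_ace
    from the same cultures' concentration curves with the growth rates held
    fixed (the integrals are closed-form, so these are linear fits); stage 3
    fits the free switching coefficients of the template to the mixed
    culture with everything else fixed.  ``stages`` stops the procedure
    early (e.g. 2 when only growth/consumption rates are wanted).  Raises
    ``CalibrationError`` when a stage is under-determined by the data
    provided.
    """
    if template is None:
        template = default_switching_model()
    if data.glucose_only is None or data.acetate_only is None:
        raise CalibrationError(
            "stage 1 under-determined: both single-substrate cultures required")

    # ---- stage 1: growth rates from exponential biomass curves
    def fit_g(df: pd.DataFrame, substrate: str) -> float:
        w = _fit_window(df, substrate) & (df["M"].to_numpy() > 0)
        if w.sum() < 3:
            raise CalibrationError(
                f"stage 1 under-determined: <3 usable points on {substrate}")
        t = df["t"].to_numpy()[w]
        return float(np.polyfit(t, np.log(df["M"].to_numpy()[w]), 1)[0])

    g_glc = fit_g(data.glucose_only, "glc")
    g_ace = fit_g(data.acetate_only, "ace")

    # ---- stage 2: consumption/production rates, growth fixed.
    # With M(t) = M0 exp(g t) the concentration curves are linear in the
    # rate:  phi(t) = phi0 -/+ rate * M0 (exp(g t) - 1)/g.
    def fit_rate(df: pd.DataFrame, column: str, g: float,
                 substrate: str) -> float:
        w = _fit_window(df, substrate)
        if w.sum() < 2:
            raise CalibrationError(
                f"stage 2 under-determined: <2 usable points for {column}")
        t = df["t"].to_numpy()[w]
        m0 = float(df["M"].to_numpy()[0])
        basis = m0 * (np.exp(g * t) - 1.0) / g
        y = df[column].to_numpy()[w] - df[column].to_numpy()[0]
        denom = float(basis @ basis)
        if denom == 0.0:
            raise CalibrationError(f"stage 2 under-determined: rank deficiency "
                                   f"fitting {column} (constant basis)")
        return float(basis @ y / denom)

    v_glc = max(0.0, -fit_rate(data.glucose_only, "glc", g_glc, "glc"))
    v_ace = max(0.0, -fit_rate(data.acetate_only, "ace", g_ace, "ace"))
    eps_ace = max(0.0, fit_rate(data.glucose_only, "ace", g_glc, "glc"))
    if stages < 3:
        return BatchModelParams(g_glc=g_glc, g_ace=g_ace, v_glc=v_glc,
                                v_ace=v_ace, eps_ace=eps_ace,
                                switching=template)

    # ---- stage 3: switching coefficients from the mixed culture
    if data.mixed is None:
        raise CalibrationError(
            "stage 3 under-determined: mixed-culture data required")
    keys = sorted(template.transitions)
    free_idx = [(key, i) for key in keys
                for i, fr in enumerate(template.transitions[key].free) if fr]
    if not free_idx:
        raise CalibrationError("stage 3: template declares no free coefficients")
    df = data.mixed
    t_eval = df["t"].to_numpy()
    m0 = float(df["M"].iloc[0])
    m_g0 = float(df["M_glc"].iloc[0]) if "M_glc" in df else m0
    m_a0 = float(df["M_ace"].iloc[0]) if "M_ace" in df else 0.0
    y0 = (m_g0, m_a0, float(df["glc"].iloc[0]), float(df["ace"].iloc[0]))
    # per-state biomass (e.g. labelled subpopulations) sharpens the fit of
    # the switching terms considerably; fall back to total biomass otherwise
    if "M_glc" in df and "M_ace" in df:
        obs_cols = ["M_glc", "M_ace", "glc", "ace"]
    else:
        obs_cols = ["M", "glc", "ace"]
    obs = np.concatenate([df[c].to_numpy() for c in obs_cols])
    scales = np.concatenate([
        np.full(len(df), max(df[c].abs().max(), 1e-12)) for c in obs_cols])
    # characteristic magnitude of each free coefficient: a rate of ~1e-3 s^-1
    # at the data's own concentration scale
    conc_scale = {"glucose": max(float(df["glc"].max()), 1e-9),
                  "acetate": max(float(df["ace"].max()), 1e-9)}
    def coeff_scale(key, i):
        tr = template.transitions[key]
        pm, pn = [(0, 0), (1, 0), (0, 1), (2, 0), (0, 2), (1, 1)][i]
        sm = conc_scale.get(tr.substrates[0], 1.0)
        sn = conc_scale.get(tr.substrates[1], 1.0)
        return 1e-3 / (sm ** pm * sn ** pn)

    x_scales = np.array([coeff_scale(k, i) for k, i in free_idx])

    def build(x):
        alphas = {k: list(template.transitions[k].alpha) for k in keys}
        for (k, i), xi, sc in zip(free_idx, x, x_scales):
            alphas[k][i] = xi * sc
        return template.with_alphas(alphas)

    def resid(x):
        sw = build(x)
        params = BatchModelParams(g_glc, g_ace, v_glc, v_ace, eps_ace, sw)
        sim = simulate_batch(params, y0, float(t_eval[-1]), t_eval=t_eval)
        pred = np.concatenate([sim[c] for c in obs_cols])
        return (pred - obs) / scales

    signs = np.array([np.sign(template.transitions[k].alpha[i]) or 1.0
                      for k, i in free_idx])
    # The cost landscape has sharp thresholds and local minima, and the
    # scaled coefficient magnitudes are only known to within a few orders.
    # Screen a coarse deterministic magnitude grid first, then polish the
    # best candidates with Levenberg-Marquardt.
    mags = (0.1, 1.0, 10.0, 100.0)
    candidates = sorted(
        ((float(np.sum(resid(np.array(m) * signs) ** 2)), np.array(m) * signs)
         for m in itertools.product(mags, repeat=len(free_idx))),
        key=lambda c: c[0])
    best = None
    for _, x0 in candidates[:3]:
        fit = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        if best is None or fit.cost < best.cost:
            best = fit
        if best.cost < 1e-10 * len(obs):
            break
    sw = build(best.x)
    return BatchModelParams(g_glc=g_glc, g_ace=g_ace, v_glc=v_glc,
                            v_ace=v_ace, eps_ace=eps_ace, switching=sw)
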