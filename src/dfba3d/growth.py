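"""Exponential biomass growth and the over-filling expansion relaxation.

Between colony updates each state's volume fraction grows exponentially with
its own last-recorded specific growth rate.  Sites pushed past the packing
limit rho_max then shed their excess through iterative Jacobi sweeps that
move (1/12) of the over-filling difference through each face — the 1/12 =
1/2 * 1/6 contains the convergence damping — until the whole colony is
within delta_rho of rho_max.  Cell volume cannot displace agar; air sites
that receive volume become cell sites; intracellular pools travel with the
volume they are dissolved in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .lattice import CELL, Lattice


@dataclass
class ExpansionReport:
    """Outcome of one expansion relaxation."""

    sweeps: int
    volume_transferred: float
    sites_converted: int
    max_residual: float
    converged: bool
    residual_history: np.ndarray

    def __str__(self) -> str:  # one line for the run log
        return (f"expansion: {self.sweeps} sweeps, "
                f"{self.sites_converted} sites converted, "
                f"residual {self.max_residual:.3e}"
                f"{'' if self.converged else ' (NOT CONVERGED)'}")


def growth_step(lattice: Lattice, t_grow: float) -> Lattice:
    """rho_i(x) <- rho_i(x) * exp(g_i(x) * t_grow) for every state at every
    cell site, with g in hr^-1 and t_grow in s."""
    factor = np.exp(lattice.growth * (t_grow / 3600.0))
    cell = lattice.site == CELL
    for s in range(lattice.rho.shape[0]):
        lattice.rho[s][cell] *= factor[s][cell]
    return lattice


def expansion_transfer(rho_i: float, rho_j: float, rho_max: float) -> float:
    """Volume fraction moved i -> j through one face in one sweep:
    (1/12) * [max(0, rho_i - rho_max) - max(0, rho_j - rho_max)].
    Negative values mean the transfer runs j -> i."""
    return (max(0.0, rho_i - rho_max) - max(0.0, rho_j - rho_max)) / 12.0


def relax_expansion(lattice: Lattice, max_sweeps: int = 10_000,
                    kmax: int | None = None) -> tuple[Lattice, ExpansionReport]:
    """Run expansion sweeps until the largest over-filling is within
    delta_rho of rho_max.  Raises on non-convergence within ``max_sweeps``.
    Conserves the summed volume fraction of every state to round-off."""
    cfg = lattice.config
    if kmax is None:
        kmax = cfg.dims[2]
    sweeps, converted, moved, hist = _kernels.relax_expansion_sweeps(
        lattice.site, lattice.rho, lattice.intra, cfg.rho_max, cfg.delta_rho,
        max_sweeps, kmax)
    residual = float(hist[-1])
    converged = residual <= cfg.delta_rho
    report = ExpansionReport(sweeps=int(sweeps),
                             volume_transferred=float(moved),
                             sites_converted=int(converted),
                             max_residual=residual, converged=converged,
                             residual_history=hist)
    if not converged:
        raise RuntimeError(f"expansion failed to converge: {report}")
    return lattice, report
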