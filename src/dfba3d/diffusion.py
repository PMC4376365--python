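"""Seven-point-stencil finite-difference diffusion with site-type-dependent
and crowding-hindered diffusivities.

Concentrations are updated as phi_i <- phi_i + (dtau/lam) * sum_j J_{j->i}
over the six face neighbours, where the face flux uses the arithmetic mean
of the two sites' diffusion coefficients:

    J_{j->i} = (D_j + D_i)/2 * (phi_j - phi_i)/lam

Air sites are clamped concentration sources; faces between air and
agar/cells are one-way so aqueous substrates cannot escape into the air.
Updates are Jacobi (simultaneous), so results are independent of traversal
order.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .lattice import AGAR, AIR, CELL, Lattice, stability_bound


def effective_diffusion(rho, d):
    """Hindered effective diffusivity in a crowded cell site:
    D_eff = D * (1 - rho) / (1 + rho/2), with rho the total cell volume
    fraction.  Accepts scalars or arrays."""
    rho_arr = np.asarray(rho)
    if np.any(rho_arr < 0) or np.any(rho_arr > 1):
        raise ValueError("rho must lie in [0, 1]")
    return d * (1.0 - rho_arr) / (1.0 + rho_arr / 2.0)


def pair_flux(phi_j, phi_i, d_j, d_i, lam):
    """Diffusive flux across the face shared by sites j and i (positive from
    j to i); antisymmetric under exchange of i and j."""
    return 0.5 * (d_j + d_i) * (phi_j - phi_i) / lam


def diffusivity_field(lattice: Lattice) -> np.ndarray:
    """Per-substrate, per-site effective diffusion coefficients:
    D_agar on agar sites, D_aq in air, and on cell sites D_aq reduced by the
    crowding factor for hindered substrates."""
    site = lattice.site
    rho_tot = lattice.total_rho()
    out = np.empty_like(lattice.ext)
    cell = site == CELL
    agar = site == AGAR
    for i, s in enumerate(lattice.substrates):
        d = out[i]
        d.fill(s.d_aq)
        d[agar] = s.d_agar
        if s.hindered:
            d[cell] = effective_diffusion(np.clip(rho_tot[cell], 0.0, 1.0),
                                          s.d_aq)
    return out


def dirichlet_indices(lattice: Lattice) -> list[tuple[int, np.ndarray, float]]:
    """(substrate index, flat site indices, value) triples for the fixed
    agar-boundary concentrations."""
    idx = np.flatnonzero(lattice.agar_boundary_mask.ravel())
    out = []
    for i, s in enumerate(lattice.substrates):
        if s.dirichlet_agar_boundary is not None:
            out.append((i, idx, s.dirichlet_agar_boundary))
    return out


def apply_dirichlet(lattice: Lattice, entries=None) -> None:
    for i, idx, value in (entries if entries is not None
                          else dirichlet_indices(lattice)):
        lattice.ext[i].ravel()[idx] = value


def diffusion_step(lattice: Lattice, dtau: float,
                   d_field: np.ndarray | None = None,
                   scratch: np.ndarray | None = None,
                   kmax: int | None = None,
                   dirichlet=None) -> Lattice:
    """Advance every substrate field by one explicit diffusion sub-step.

    ``d_field`` may be passed to reuse diffusivities between sub-steps (they
    only change when the colony does); ``kmax`` restricts the sweep to
    k < kmax (everything above must be air, which is static).
    Raises on a violated stability bound or on fields driven below the
    -1e-15 M negativity tolerance.
    """
    cfg = lattice.config
    if d_field is None:
        d_field = diffusivity_field(lattice)
    d_present = max((s.d_aq for s in lattice.substrates), default=0.0)
    if d_present > 0 and dtau > stability_bound(cfg.lam, d_present):
        raise ValueError("dtau exceeds the stencil stability bound")
    if scratch is None:
        scratch = np.empty_like(lattice.ext)
    nz = cfg.dims[2]
    if kmax is None:
        kmax = nz
    fac = dtau / cfg.lam**2
    for i, s in enumerate(lattice.substrates):
        _kernels.diffuse_substrate(lattice.ext[i], scratch[i], lattice.site,
                                   d_field[i], s.air_value, fac, kmax)
        lattice.ext[i][:, :, :kmax] = scratch[i][:, :, :kmax]
    apply_dirichlet(lattice, dirichlet)
    lo = lattice.ext.min()
    if not np.isfinite(lo) or lo < -1e-15:
        raise FloatingPointError(
            f"diffusion instability: min concentration {lo:g} M")
    return lattice
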