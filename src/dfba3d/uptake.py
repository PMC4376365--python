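"""Michaelis-Menten active import: extracellular -> intracellular pools.

Actively transported substrates (glucose) are moved from the shared
extracellular field into a per-site intracellular pool at the rate

    k(x,t) = rho(x,t) * (E k_cat / V_cell) * phi_ext / (k_m + phi_ext)

where E k_cat / V_cell is derived from the specific maximum uptake rate
(mmol gDwt^-1 hr^-1) via the single-cell dry mass over volume.  The pool is
shared per site; the FBA layer later divides it by the total volume fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernels, units
from .lattice import ACTIVE, Lattice


@dataclass(frozen=True)
class UptakeKinetics:
    """Michaelis-Menten import kinetics for one active substrate."""

    vmax_specific: float   # mmol gDwt^-1 hr^-1 (= E k_cat / m_cell)
    km: float              # mol l^-1
    m_cell: float          # g
    v_cell: float          # m^3

    def __post_init__(self) -> None:
        if self.vmax_specific <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")

    @property
    def vmax_volumetric(self) -> float:
        """E k_cat / V_cell expressed as mol l^-1 s^-1 at volume fraction 1."""
        return units.specific_to_volumetric(self.vmax_specific, self.m_cell,
                                            self.v_cell)


def uptake_rate(rho: float, kinetics: UptakeKinetics, phi_ext: float) -> float:
    """Instantaneous local uptake rate, mol l^-1 s^-1."""
    if rho < 0 or phi_ext < 0:
        raise ValueError("inputs must be non-negative")
    return rho * kinetics.vmax_volumetric * phi_ext / (kinetics.km + phi_ext)


def active_uptake_step(lattice: Lattice, dtau: float,
                       rho_tot=None, kmax: int | None = None) -> dict[str, int]:
    """Advance every active substrate's ext/int pools by one sub-step.

    The transfer is capped at phi_ext so the extracellular pool can never go
    negative within a sub-step; the per-substrate cap counts are returned as
    a diagnostics dict.  phi_ext + phi_int is conserved per site exactly.
    """
    cfg = lattice.config
    if rho_tot is None:
        rho_tot = lattice.total_rho()
    if kmax is None:
        kmax = cfg.dims[2]
    capped: dict[str, int] = {}
    for s in lattice.substrates:
        if s.transport != ACTIVE:
            continue
        kin = UptakeKinetics(s.uptake_vmax, s.uptake_km, cfg.m_cell, cfg.v_cell)
        n = _kernels.mm_uptake(lattice.ext_field(s.name),
                               lattice.intra_field(s.name),
                               rho_tot, lattice.site,
                               kin.vmax_volumetric, s.uptake_km, dtau, kmax)
        capped[s.name] = int(n)
    return capped
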