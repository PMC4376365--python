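"""Simulation geometry: the cubic lattice, site typing and parameter defaults.

A simulation volume is a 3D cubic lattice of spacing ``lam``; the bottom slab
of height ``agar_height`` is agar, everything above starts as air, and the
colony occupies cell-type sites that appear as it expands.  Cell material is
a continuous per-site volume fraction (one field per regulatory state), and
every tracked chemical species is a per-site concentration field in mol l^-1.

Coordinates are 0-based integer triples ``(i, j, k)``; ``k`` increases upward
from the agar floor and the physical centre of a site is ``(i + 1/2) * lam``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: site-type codes stored in the uint8 site grid
AIR = np.uint8(0)
AGAR = np.uint8(1)
CELL = np.uint8(2)

PASSIVE = "passive"
ACTIVE = "active"


def stability_bound(lam: float, d_max: float) -> float:
    """Largest diffusion sub-step lam**2 / (2 * d_max) for an explicit
    seven-point stencil, in seconds."""
    if lam <= 0 or d_max <= 0:
        raise ValueError("lam and d_max must be positive")
    return lam * lam / (2.0 * d_max)


def henry_concentration(partial_pressure: float, henry_constant: float) -> float:
    """Dissolved-gas concentration (mol l^-1) from a partial pressure (atm)
    and a Henry's-law constant (mol l^-1 atm^-1)."""
    if partial_pressure < 0 or henry_constant < 0:
        raise ValueError("inputs must be non-negative")
    return partial_pressure * henry_constant


def cells_per_site(rho_max: float, lam: float, v_cell: float) -> float:
    """Number of cells held by one lattice site filled to ``rho_max``."""
    if rho_max < 0 or lam <= 0 or v_cell <= 0:
        raise ValueError("inputs must be positive (rho_max may be 0)")
    return rho_max * lam**3 / v_cell


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice geometry, numerical time steps and cell-packing parameters.

    Defaults reproduce the headline simulation conditions: a
    3.2 x 3.2 x 1.92 mm volume at 10 um spacing with a 0.96 mm agar slab,
    1 ms diffusion/uptake/FBA sub-steps, 1 s steady-state relaxation windows
    and 60 s colony updates.
    """

    dims: tuple[int, int, int] = (320, 320, 192)
    lam: float = 1.0e-5            # lattice spacing, m
    agar_height: float = 0.96e-3   # m
    dtau: float = 1.0e-3           # diffusion/uptake/FBA sub-step, s
    t_ss: float = 1.0              # steady-state relaxation window, s
    t_grow: float = 60.0           # colony-update interval, s
    rho_max: float = 0.65          # max packed cell volume fraction
    delta_rho: float = 0.01        # expansion convergence cutoff
    m_cell: float = 2.58e-13       # dry mass per cell, g
    v_cell: float = 1.0e-18        # volume per cell, m^3

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        for name in ("lam", "agar_height", "dtau", "t_ss", "t_grow",
                     "m_cell", "v_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.rho_max < 1.0:
            raise ValueError("rho_max must lie in (0, 1)")
        if not 0.0 < self.delta_rho < self.rho_max:
            raise ValueError("delta_rho must lie in (0, rho_max)")
        if self.t_ss > self.t_grow:
            raise ValueError("t_ss must not exceed t_grow")

    @property
    def n_agar_layers(self) -> int:
        return int(round(self.agar_height / self.lam))

    def with_(self, **kw) -> "LatticeConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class SubstrateSpec:
    """Physical and kinetic description of one tracked chemical species.

    ``air_value`` is the fixed concentration in air-type sites: the dissolved
    equilibrium concentration for volatile species (oxygen), 0 for aqueous
    ones (glucose, acetate) which cannot escape into the air.
    ``dirichlet_agar_boundary`` (if given) pins the concentration on the agar
    walls and floor.  Active substrates carry Michaelis-Menten import
    kinetics (``uptake_vmax`` mmol gDwt^-1 hr^-1, ``uptake_km`` mol l^-1);
    hindered substrates diffuse around cells and are slowed inside the colony.
    """

    name: str
    d_aq: float                      # diffusivity in water, m^2 s^-1
    d_agar: float                    # diffusivity in agar, m^2 s^-1
    transport: str = PASSIVE
    hindered: bool = False
    air_value: float = 0.0           # mol l^-1
    dirichlet_agar_boundary: Optional[float] = None
    uptake_vmax: Optional[float] = None   # mmol gDwt^-1 hr^-1
    uptake_km: Optional[float] = None     # mol l^-1

    def __post_init__(self) -> None:
        if self.d_aq <= 0 or self.d_agar <= 0:
            raise ValueError("diffusivities must be positive")
        if self.transport not in (PASSIVE, ACTIVE):
            raise ValueError("transport must be 'passive' or 'active'")
        if self.transport == ACTIVE:
            if self.uptake_vmax is None or self.uptake_km is None:
                raise ValueError("active substrates need uptake_vmax and uptake_km")
            if self.uptake_vmax <= 0 or self.uptake_km <= 0:
                raise ValueError("uptake kinetics must be positive")
        else:
            if self.uptake_vmax is not None or self.uptake_km is not None:
                raise ValueError("passive substrates must not define uptake kinetics")
        if self.air_value < 0:
            raise ValueError("air_value must be non-negative")


def default_substrates(glucose_g_per_l: float = 2.5) -> list[SubstrateSpec]:
    """Glucose, oxygen and acetate with their literature diffusivities and
    boundary conditions.  ``glucose_g_per_l`` sets the agar reservoir
    concentration (2.5 g l^-1 = 1.39e-2 M by default; the concentration sweep
    uses 1.25-10 g l^-1)."""
    glc_m = glucose_g_per_l / 180.16  # molar mass of glucose, g mol^-1
    return [
        SubstrateSpec("glucose", d_aq=7.8e-10, d_agar=7.4e-10, transport=ACTIVE,
                      hindered=True, air_value=0.0, dirichlet_agar_boundary=glc_m,
                      uptake_vmax=10.4, uptake_km=3.7e-4),
        SubstrateSpec("oxygen", d_aq=2.6e-9, d_agar=2.5e-9, transport=PASSIVE,
                      hindered=False, air_value=2.6e-4,
                      dirichlet_agar_boundary=2.6e-4),
        SubstrateSpec("acetate", d_aq=1.2e-9, d_agar=1.1e-9, transport=PASSIVE,
                      hindered=True, air_value=0.0, dirichlet_agar_boundary=0.0),
    ]


@dataclass
class Lattice:
    """State of one simulation: geometry plus all per-site fields.

    Fields
    ------
    site : (nx, ny, nz) uint8 grid of AIR/AGAR/CELL codes.
    ext : (n_substrates, nx, ny, nz) extracellular concentrations, M.
    intra : (n_active, nx, ny, nz) intracellular pools of actively imported
        substrates, M of lattice-site volume.
    rho : (n_states, nx, ny, nz) per-state cell volume fractions.
    growth : (n_states, nx, ny, nz) last-recorded specific growth rates, hr^-1.
    vex : (n_states, n_tracked, nx, ny, nz) last-recorded exchange fluxes
        (uptake positive), mmol gDwt^-1 hr^-1; populated by the driver.
    """

    config: LatticeConfig
    substrates: list[SubstrateSpec]
    state_ids: tuple[str, ...]
    site: np.ndarray
    ext: np.ndarray
    intra: np.ndarray
    rho: np.ndarray
    growth: np.ndarray
    vex: Optional[np.ndarray] = None
    drift: Optional[np.ndarray] = None   # per-substrate field drift rate, M/s
    tracked_names: Optional[tuple[str, ...]] = None  # vex substrate order
    seed_site: Optional[tuple[int, int, int]] = None
    #: boolean mask of agar-boundary (walls + floor) sites, for Dirichlet resets
    agar_boundary_mask: np.ndarray = field(default=None, repr=False)

    # -- index helpers -----------------------------------------------------
    def sub_index(self, name: str) -> int:
        for i, s in enumerate(self.substrates):
            if s.name == name:
                return i
        raise KeyError(name)

    def state_index(self, state_id: str) -> int:
        return self.state_ids.index(state_id)

    @property
    def active_substrates(self) -> list[SubstrateSpec]:
        return [s for s in self.substrates if s.transport == ACTIVE]

    def active_index(self, name: str) -> int:
        for i, s in enumerate(self.active_substrates):
            if s.name == name:
                return i
        raise KeyError(name)

    def ext_field(self, name: str) -> np.ndarray:
        return self.ext[self.sub_index(name)]

    def intra_field(self, name: str) -> np.ndarray:
        return self.intra[self.active_index(name)]

    def total_rho(self) -> np.ndarray:
        return self.rho.sum(axis=0)

    @property
    def n_agar_layers(self) -> int:
        return self.config.n_agar_layers

    def copy(self) -> "Lattice":
        return Lattice(
            config=self.config, substrates=list(self.substrates),
            state_ids=self.state_ids, site=self.site.copy(),
            ext=self.ext.copy(), intra=self.intra.copy(), rho=self.rho.copy(),
            growth=self.growth.copy(),
            vex=None if self.vex is None else self.vex.copy(),
            drift=None if self.drift is None else self.drift.copy(),
            tracked_names=self.tracked_names,
            seed_site=self.seed_site,
            agar_boundary_mask=self.agar_boundary_mask,
        )


def build_lattice(config: LatticeConfig,
                  substrates: Sequence[SubstrateSpec],
                  state_ids: Sequence[str] = ("cells",)) -> Lattice:
    """Construct and initialize a lattice: AGAR slab at the bottom, AIR above,
    substrate fields at their boundary/air values, no cells.

    Raises ``ValueError`` if ``config.dtau`` violates the explicit-stencil
    stability bound for the fastest-diffusing substrate present.
    """
    if substrates:
        d_max = max(s.d_aq for s in substrates)
        bound = stability_bound(config.lam, d_max)
        if config.dtau > bound:
            raise ValueError(
                f"unstable stencil: dtau={config.dtau:g} s exceeds "
                f"lam^2/(2 D_max)={bound:g} s")
    nx, ny, nz = config.dims
    n_agar = config.n_agar_layers
    if n_agar >= nz:
        raise ValueError("agar_height must be smaller than the z extent")

    site = np.full(config.dims, AIR, dtype=np.uint8)
    site[:, :, :n_agar] = AGAR

    ext = np.zeros((len(substrates), nx, ny, nz))
    for i, s in enumerate(substrates):
        ext[i][site == AIR] = s.air_value
        agar_init = s.dirichlet_agar_boundary
        if agar_init is not None:
            ext[i][site == AGAR] = agar_init

    n_active = sum(1 for s in substrates if s.transport == ACTIVE)
    n_states = len(state_ids)
    intra = np.zeros((max(n_active, 1), nx, ny, nz)) if n_active else \
        np.zeros((0, nx, ny, nz))
    rho = np.zeros((n_states, nx, ny, nz))
    growth = np.zeros((n_states, nx, ny, nz))

    boundary = np.zeros(config.dims, dtype=bool)
    boundary[0, :, :n_agar] = True
    boundary[-1, :, :n_agar] = True
    boundary[:, 0, :n_agar] = True
    boundary[:, -1, :n_agar] = True
    boundary[:, :, 0] = True  # agar floor
    boundary &= site == AGAR

    return Lattice(config=config, substrates=list(substrates),
                   state_ids=tuple(state_ids), site=site, ext=ext, intra=intra,
                   rho=rho, growth=growth, agar_boundary_mask=boundary)


def seed_colony(lattice: Lattice, state_id: str, volume_fraction: float,
                site: Optional[tuple[int, int, int]] = None) -> Lattice:
    """Seed cell volume at an air-type site directly on the agar surface
    (defaults to the central surface site).  Converts the site to cell type
    and initializes its aqueous substrate concentrations to 0 (volatile ones
    to their air value); diffusion re-equilibrates them within the next
    relaxation window.
    """
    cfg = lattice.config
    if not 0.0 < volume_fraction <= cfg.rho_max:
        raise ValueError("volume_fraction must lie in (0, rho_max]")
    if site is None:
        site = (cfg.dims[0] // 2, cfg.dims[1] // 2, cfg.n_agar_layers)
    i, j, k = site
    code = lattice.site[i, j, k]
    if code == AGAR:
        raise ValueError("cannot seed inside the agar")
    if k != cfg.n_agar_layers and code == AIR:
        raise ValueError("seed site must sit directly on the agar surface")
    was_air = code == AIR
    lattice.site[i, j, k] = CELL
    if was_air:
        for si, s in enumerate(lattice.substrates):
            lattice.ext[si, i, j, k] = s.air_value
    lattice.rho[lattice.state_index(state_id), i, j, k] += volume_fraction
    if lattice.rho[:, i, j, k].sum() > cfg.rho_max + cfg.delta_rho:
        raise ValueError("seeding would over-fill the site")
    if lattice.seed_site is None:
        lattice.seed_site = site
    return lattice
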