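"""Ready-made simulation scenarios.

The scaled-down colony scenario reproduces, on a 64 x 64 x 48 lattice with
the toy metabolic model, the qualitative structure of a dense colony on
glucose minimal agar: an anoxic interior, acetate secretion by fermenting
cells near the agar, acetate consumption by oxygenated cells above and
outside them, and late-phase linear radial expansion.  The colony is seeded
with one site at the packing limit (~650 cells, an established
microcolony): from a single cell the toy model's ~43-min doubling time
cannot produce a colony thicker than the oxygen penetration depth within
the simulated half-day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .driver import (ColonySummary, run_colony_simulation, summaries_frame)
from .fixtures import build_toy_model, toy_states
from .lattice import (CELL, Lattice, LatticeConfig, build_lattice,
                      default_substrates, seed_colony)
from .metabolism import FluxTable, MetabolicModel, build_flux_table
from .regulation import SwitchingModel, default_switching_model


def scaled_colony_config(shape: tuple[int, int, int] = (64, 64, 48),
                         agar_layers: int = 16) -> LatticeConfig:
    """Numerical conditions of the scaled-down colony runs: 10 um lattice,
    160 um agar slab, 4 ms sub-steps (a factor ~5 below the lam^2/(2 D_O2)
    bound), 1 s relaxation windows, 2 min colony updates."""
    return LatticeConfig(dims=shape, lam=1.0e-5,
                         agar_height=agar_layers * 1.0e-5,
                         dtau=4.0e-3, t_ss=1.0, t_grow=120.0)


@dataclass
class ScenarioResult:
    variant: str
    lattice: Lattice
    summaries: list[ColonySummary]
    table: FluxTable
    model: MetabolicModel

    @property
    def frame(self) -> pd.DataFrame:
        return summaries_frame(self.summaries)


def run_colony_scenario(variant: str = "regulated",
                        hours: float = 12.0,
                        shape: tuple[int, int, int] = (64, 64, 48),
                        glucose_g_per_l: float = 2.5,
                        crowding: bool = False,
                        n_nodes: int = 9,
                        table: Optional[FluxTable] = None,
                        switching: Optional[SwitchingModel] = None,
                        ) -> ScenarioResult:
    """Build and run one scaled-down colony variant end to end.

    ``variant`` is 'unregulated', 'regulated' or 'non-crossfeeding';
    ``glucose_g_per_l`` supports the agar glucose concentration sweep.
    A prebuilt flux ``table`` may be reused between variants that share
    states.  Entirely deterministic.
    """
    model = build_toy_model(crowding=crowding)
    states = toy_states(variant)
    if table is None:
        table = build_flux_table(model, states, n_nodes=n_nodes,
                                 crowding=crowding)
    cfg = scaled_colony_config(shape)
    lattice = build_lattice(cfg, default_substrates(glucose_g_per_l),
                            state_ids=[s.id for s in states])
    seed_colony(lattice, states[0].id, cfg.rho_max)
    if switching is None and variant == "regulated":
        switching = default_switching_model()
    if variant != "regulated":
        switching = None
    lattice, summaries = run_colony_simulation(lattice, table,
                                               switching=switching,
                                               hours=hours)
    return ScenarioResult(variant=variant, lattice=lattice,
                          summaries=summaries, table=table, model=model)


def anoxic_fraction(lattice: Lattice, threshold: float = 0.01) -> float:
    """Fraction of cell sites whose oxygen is below ``threshold`` of the
    air value."""
    o2 = lattice.ext_field("oxygen")
    spec = lattice.substrates[lattice.sub_index("oxygen")]
    cells = lattice.site == CELL
    if not cells.any():
        return 0.0
    return float((o2[cells] < threshold * spec.air_value).mean())


def acetate_flux_maps(lattice: Lattice):
    """(secretion, uptake) 3D maps of the volumetric acetate exchange,
    mmol gDwt^-1 hr^-1 weighted by each state's volume fraction."""
    if lattice.vex is None or lattice.tracked_names is None:
        raise ValueError("run a steady-state cycle first")
    t = lattice.tracked_names.index("acetate")
    v = (lattice.vex[:, t] * lattice.rho).sum(axis=0)
    return np.maximum(-v, 0.0), np.maximum(v, 0.0)
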