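import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from dfba3d.fixtures import build_toy_model, toy_states
from dfba3d.lattice import (LatticeConfig, SubstrateSpec, build_lattice,
                            default_substrates, seed_colony)
from dfba3d.metabolism import build_flux_table


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model()


@pytest.fixture(scope="session")
def toy_model_crowded():
    return build_toy_model(crowding=True)


@pytest.fixture(scope="session")
def toy_table(toy_model):
    """Coarse (5-node) lookup table for the unregulated toy state."""
    return build_flux_table(toy_model, toy_states("unregulated"), n_nodes=5)


@pytest.fixture(scope="session")
def toy_table_regulated(toy_model):
    return build_flux_table(toy_model, toy_states("regulated"), n_nodes=5)


def small_config(**kw):
    defaults = dict(dims=(8, 8, 8), lam=1e-5, agar_height=3e-5, dtau=1e-3,
                    t_ss=0.05, t_grow=60.0)
    defaults.update(kw)
    return LatticeConfig(**defaults)


@pytest.fixture
def small_lattice():
    """8x8x8 lattice with the standard three substrates and one state."""
    cfg = small_config()
    return build_lattice(cfg, default_substrates(), state_ids=("cells",))


@pytest.fixture
def seeded_lattice(small_lattice):
    return seed_colony(small_lattice, "cells", 0.1)


def closed_cell_lattice(n=5, substrate=None, states=("cells",)):
    """An all-cell cube with no air, no agar and no Dirichlet boundaries:
    a closed domain for conservation checks."""
    subs = [substrate or SubstrateSpec("tracer", d_aq=2.6e-9, d_agar=2.5e-9,
                                       transport="active", uptake_vmax=10.0,
                                       uptake_km=1e-4)]
    cfg = LatticeConfig(dims=(n, n, n), lam=1e-5, agar_height=1e-5 * 0.5,
                        dtau=1e-3, t_ss=0.05, t_grow=60.0)
    # agar_height below one layer -> zero agar layers
    lat = build_lattice(cfg, subs, state_ids=states)
    lat.site[:] = 2  # CELL everywhere
    lat.agar_boundary_mask = np.zeros(cfg.dims, dtype=bool)
    return lat
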