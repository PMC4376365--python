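"""File formats: VTK image-data snapshots, YAML run configs, summary CSVs
and flux-table persistence (see :mod:`.metabolism` for the HDF5 layout).

VTK output uses the legacy ASCII STRUCTURED_POINTS format — plain text,
readable by ParaView/VisIt — with one scalar field per substrate and per
cell state.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .driver import summaries_frame
from .lattice import (Lattice, LatticeConfig, SubstrateSpec,
                      default_substrates)
from .metabolism import CellState


def write_vtk_image(path: str, fields: Mapping[str, np.ndarray],
                    spacing: float, origin=(0.0, 0.0, 0.0)) -> None:
    """Write 3D scalar fields on a common grid as legacy ASCII VTK
    STRUCTURED_POINTS.  Point data is emitted in VTK's x-fastest order."""
    fields = dict(fields)
    if not fields:
        raise ValueError("no fields to write")
    shapes = {f.shape for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    nx, ny, nz = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("dfba3d lattice snapshot\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:g} {origin[1]:g} {origin[2]:g}\n")
        fh.write(f"SPACING {spacing:g} {spacing:g} {spacing:g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.9g")


def snapshot_fields(lattice: Lattice) -> dict[str, np.ndarray]:
    """Standard snapshot contents: site types, substrate fields, per-state
    volume fractions and growth rates."""
    out: dict[str, np.ndarray] = {"site_type": lattice.site.astype(float)}
    for i, s in enumerate(lattice.substrates):
        out[f"conc_{s.name}"] = lattice.ext[i]
    for i, sid in enumerate(lattice.state_ids):
        out[f"rho_{sid}"] = lattice.rho[i]
        out[f"growth_{sid}"] = lattice.growth[i]
    if lattice.vex is not None and lattice.tracked_names is not None:
        for t, name in enumerate(lattice.tracked_names):
            out[f"vex_{name}"] = (lattice.vex[:, t] * lattice.rho).sum(axis=0)
    return out


def write_checkpoint(out_dir: str, cycle: int, lattice: Lattice,
                     manifest: str = "checkpoints.csv") -> str:
    """Write a VTK snapshot and append (cycle, time, file) to the CSV
    manifest; returns the snapshot path."""
    os.makedirs(out_dir, exist_ok=True)
    fname = f"snapshot_{cycle:06d}.vtk"
    path = os.path.join(out_dir, fname)
    write_vtk_image(path, snapshot_fields(lattice), spacing=lattice.config.lam)
    mpath = os.path.join(out_dir, manifest)
    row = pd.DataFrame([{"cycle": cycle,
                         "time_hr": cycle * lattice.config.t_grow / 3600.0,
                         "file": fname}])
    row.to_csv(mpath, mode="a", header=not os.path.exists(mpath), index=False)
    return path


def write_summaries(path: str, summaries) -> None:
    summaries_frame(summaries).to_csv(path, index=False)


# --------------------------------------------------------------------------
# run configuration files
# --------------------------------------------------------------------------

def load_config(path: str):
    """Read a YAML run config.

    Sections: ``lattice`` (LatticeConfig fields), ``substrates`` (name ->
    SubstrateSpec fields; omit for the glucose/oxygen/acetate defaults),
    ``states`` (id -> uptake_caps mapping) and ``run`` (free-form options
    passed through).  Returns (LatticeConfig, [SubstrateSpec], [CellState],
    run_options).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    lat = raw.get("lattice", {})
    if "dims" in lat:
        lat["dims"] = tuple(int(x) for x in lat["dims"])
    config = LatticeConfig(**lat)
    subs_raw = raw.get("substrates")
    if subs_raw is None:
        substrates = default_substrates(
            raw.get("run", {}).get("glucose_g_per_l", 2.5))
    else:
        substrates = [SubstrateSpec(name=name, **spec)
                      for name, spec in subs_raw.items()]
    states = [CellState(sid, dict(spec.get("uptake_caps", {})))
              for sid, spec in raw.get("states", {"cells": {}}).items()]
    return config, substrates, states, raw.get("run", {})


def dump_config(path: str, config: LatticeConfig,
                substrates: Optional[list[SubstrateSpec]] = None,
                states: Optional[list[CellState]] = None,
                run: Optional[dict] = None) -> None:
    """Write the fully resolved run configuration (for run metadata)."""
    doc: dict = {"lattice": {
        "dims": list(config.dims), "lam": config.lam,
        "agar_height": config.agar_height, "dtau": config.dtau,
        "t_ss": config.t_ss, "t_grow": config.t_grow,
        "rho_max": config.rho_max, "delta_rho": config.delta_rho,
        "m_cell": config.m_cell, "v_cell": config.v_cell}}
    if substrates is not None:
        doc["substrates"] = {
            s.name: {k: v for k, v in s.__dict__.items()
                     if k != "name" and v is not None}
            for s in substrates}
    if states is not None:
        doc["states"] = {st.id: {"uptake_caps": dict(st.uptake_caps)}
                         for st in states}
    if run:
        doc["run"] = dict(run)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
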