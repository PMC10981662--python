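"""Checkpoint and table I/O.

Field/density states are stored in HDF5 with full grid and model metadata,
so any run can be warm-started or post-processed from its checkpoint.
Tabular outputs (residual histories, tension sweeps) are plain CSV via
pandas with a fixed float format, which makes repeated runs byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from .geometry import Grid
from .params import ModelParams
from .scft import DensityState, FieldState

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "write_residuals_csv",
    "write_table_csv",
]

_FLOAT_FMT = "%.10g"


def save_checkpoint(path, fields: FieldState, dens: DensityState | None,
                    grid: Grid, params: ModelParams, mu: float | None = None,
                    meta: dict | None = None) -> None:
    """Write a state checkpoint (fields, densities, grid, params) to HDF5."""
    with h5py.File(path, "w") as h5:
        gf = h5.create_group("fields")
        gf.create_dataset("w_A", data=fields.w_A)
        gf.create_dataset("w_B", data=fields.w_B)
        gf.create_dataset("xi", data=fields.xi)
        if dens is not None:
            gd = h5.create_group("densities")
            gd.create_dataset("phi_tail", data=dens.phi_tail)
            gd.create_dataset("phi_head", data=dens.phi_head)
            gd.create_dataset("phi_solvent", data=dens.phi_solvent)
        gg = h5.create_group("grid")
        gg.attrs["kind"] = grid.kind
        gg.attrs["shape"] = grid.shape
        gg.attrs["spacings"] = grid.spacings
        gg.attrs["boundary"] = [b for b in grid.boundary]
        gp = h5.create_group("params")
        for k, v in asdict(params).items():
            gp.attrs[k] = v
        if mu is not None:
            h5.attrs["mu"] = float(mu)
        h5.attrs["meta"] = json.dumps(meta or {}, sort_keys=True)


def load_checkpoint(path) -> tuple[FieldState, DensityState | None, Grid,
                                   ModelParams, dict]:
    """Read a checkpoint written by :func:`save_checkpoint`."""
    with h5py.File(path, "r") as h5:
        gf = h5["fields"]
        fields = FieldState(gf["w_A"][...], gf["w_B"][...], gf["xi"][...])
        dens = None
        if "densities" in h5:
            gd = h5["densities"]
            dens = DensityState(gd["phi_tail"][...], gd["phi_head"][...],
                                gd["phi_solvent"][...])
        gg = h5["grid"]
        grid = Grid(kind=str(gg.attrs["kind"]),
                    shape=tuple(int(n) for n in gg.attrs["shape"]),
                    spacings=tuple(float(s) for s in gg.attrs["spacings"]),
                    boundary=tuple(str(b) for b in gg.attrs["boundary"]))
        pa = dict(h5["params"].attrs)
        params = ModelParams(chiN=float(pa["chiN"]), f=float(pa["f"]),
                             solvent_ratio=float(pa["solvent_ratio"]),
                             mu=float(pa["mu"]), ds=float(pa["ds"]))
        meta = json.loads(h5.attrs.get("meta", "{}"))
        if "mu" in h5.attrs:
            meta["mu"] = float(h5.attrs["mu"])
    return fields, dens, grid, params, meta


def write_residuals_csv(path, history, free_energy: float | None = None,
                        meta: dict | None = None) -> None:
    """Residual history as CSV (iteration, residual), with meta as header."""
    df = pd.DataFrame({"iteration": np.arange(len(history)),
                       "residual": np.asarray(history, dtype=float)})
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        if free_energy is not None:
            fh.write(f"# free_energy: {free_energy!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_table_csv(path, rows: list[dict], meta: dict | None = None) -> None:
    """Generic table writer with deterministic formatting."""
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)
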