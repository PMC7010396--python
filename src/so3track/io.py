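"""Portable containers: chart fields as .npz with embedded grid metadata,
paths and centerlines as delimited text tables."""

from __future__ import annotations

import json

import numpy as np

from .grid import ChartGrid, ScalarField3D

__all__ = ["save_field", "load_field", "save_table", "load_table"]


def save_field(path, fld: ScalarField3D, **extra_meta):
    g = fld.grid
    meta = {
        "axes": ["x", "y", "theta"],
        "nx": g.nx,
        "ny": g.ny,
        "nt": g.nt,
        "x_cap": g.x_cap,
        "spacings": [g.hx, g.hy, g.ht],
        "periodic": [False, True, True],
        "seed": list(fld.seed) if fld.seed is not None else None,
        "interp_order": fld.interp_order,
        **extra_meta,
    }
    np.savez_compressed(path, values=fld.values, meta=json.dumps(meta))


def load_field(path) -> ScalarField3D:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        grid = ChartGrid(nx=meta["nx"], ny=meta["ny"], nt=meta["nt"], x_cap=meta["x_cap"])
        seed = tuple(meta["seed"]) if meta.get("seed") else None
        return ScalarField3D(
            values=z["values"], grid=grid,
            interp_order=meta.get("interp_order", 3), seed=seed,
        )


def save_table(path, array, header):
    np.savetxt(path, np.asarray(array), header=" ".join(header), fmt="%.12g")


def load_table(path):
    return np.loadtxt(path)
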