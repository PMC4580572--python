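"""File plumbing: TIFF stacks, CSV traces, HDF5 volumes, NIfTI, YAML, JSON.

All writers round-trip losslessly at numeric precision; readers fail fast
with the offending file and field named.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import Grid
from .motion import MotionTrace

__all__ = [
    "write_tiff_stack",
    "read_tiff_stack",
    "write_trace_csv",
    "read_trace_csv",
    "write_volume_h5",
    "read_volume_h5",
    "write_nifti",
    "read_nifti",
    "load_yaml_config",
    "write_json_report",
]


def write_tiff_stack(frames: np.ndarray, path: str | Path) -> None:
    """Write a (n, H, W) grayscale stack as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(frames), photometric='minisblack')


def read_tiff_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_trace_csv(trace: MotionTrace, path: str | Path) -> None:
    """Write a motion trace as CSV with header ``t_s,dx_mm,dz_mm[,dy_mm]``."""
    data = {"t_s": trace.t, "dx_mm": trace.dx, "dz_mm": trace.dz}
    if trace.dy is not None:
        data["dy_mm"] = trace.dy
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t_s", "dx_mm", "dz_mm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    dy = df["dy_mm"].to_numpy() if "dy_mm" in df.columns else None
    return MotionTrace(df["t_s"].to_numpy(), df["dx_mm"].to_numpy(), df["dz_mm"].to_numpy(), dy)


def _grid_attrs(g: h5py.Group, grid: Grid) -> None:
    g.attrs["origin_mm"] = grid.origin
    g.attrs["spacing_mm"] = grid.spacing


def write_volume_h5(
    path: str | Path, datasets: dict[str, np.ndarray], grid: Grid, attrs: dict | None = None
) -> None:
    """Write named 3D volumes sharing one grid, with grid metadata."""
    with h5py.File(str(path), "w") as f:
        _grid_attrs(f, grid)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for name, arr in datasets.items():
            f.create_dataset(name, data=arr)


def read_volume_h5(path: str | Path) -> tuple[dict[str, np.ndarray], Grid, dict]:
    with h5py.File(str(path), "r") as f:
        if "origin_mm" not in f.attrs or "spacing_mm" not in f.attrs:
            raise ValueError(f"{path}: missing grid metadata (origin_mm/spacing_mm)")
        data = {name: f[name][()] for name in f.keys()}
        shape = next(iter(data.values())).shape
        grid = Grid(tuple(f.attrs["origin_mm"]), tuple(f.attrs["spacing_mm"]), tuple(shape))
        attrs = {
            k: v for k, v in f.attrs.items() if k not in ("origin_mm", "spacing_mm")
        }
    return data, grid, attrs


def write_nifti(array: np.ndarray, grid: Grid, path: str | Path) -> None:
    """Write a volume as NIfTI with the grid spacing/origin in the affine."""
    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin
    img = nib.Nifti1Image(np.asarray(array), affine)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    aff = img.affine
    grid = Grid(tuple(aff[:3, 3]), tuple(np.diag(aff)[:3]), arr.shape)
    return arr, grid


def load_yaml_config(path: str | Path, valid_keys: set[str]) -> dict:
    """Load a YAML mapping, rejecting unknown top-level keys."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - valid_keys
    if unknown:
        raise ValueError(
            f"{path}: unknown keys {sorted(unknown)}; valid keys are {sorted(valid_keys)}"
        )
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(_jsonable(report), f, indent=2, sort_keys=True)
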