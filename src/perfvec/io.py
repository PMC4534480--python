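"""Readers and writers for the package's interchange formats.

Formats:

* Surface-grid CSV — header ``index,x_mm,y_mm,z_mm,area_mm2,weight``, one
  row per rectangle, index contiguous from 0, values at 9 significant
  digits. Coordinates are cardiac-frame millimetres.
* Voxel volumes — NIfTI-1 via nibabel, voxel spacing in the header, array
  axes matching the cardiac frame.
* Perfusion results — JSON ``{phase, C_A, C_P, P, magnitude}`` in mm.
* Cohort tables — CSV with the columns of
  :data:`perfvec.phantom.COHORT_COLUMNS`.
* Run configuration — a single YAML file mirroring the spec dataclasses.

Malformed input is rejected with a named error, never silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateGridError, ParameterError, SchemaError
from .phantom import (
    COHORT_COLUMNS,
    AcquisitionSpec,
    CohortSpec,
    DefectSpec,
    VoxelVolume,
)
from .surface import GridResolution, LVShapeSpec, SurfaceGrid
from .vector import PerfusionResult

__all__ = [
    "SURFACE_COLUMNS",
    "read_surface_csv",
    "write_surface_csv",
    "read_volume",
    "write_volume",
    "write_result_json",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_config",
]

SURFACE_COLUMNS = ["index", "x_mm", "y_mm", "z_mm", "area_mm2", "weight"]


def write_surface_csv(grid: SurfaceGrid, path: str | Path) -> None:
    """Write the grid as CSV with 9 significant digits per value."""
    df = pd.DataFrame(
        {
            "index": grid.index,
            "x_mm": grid.centers[:, 0],
            "y_mm": grid.centers[:, 1],
            "z_mm": grid.centers[:, 2],
            "area_mm2": grid.areas,
            "weight": grid.weights,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_surface_csv(path: str | Path) -> SurfaceGrid:
    """Read a surface grid, validating the schema strictly.

    Parametric metadata (normals, angles, arc positions) is not part of the
    CSV format, so the returned grid carries ``None`` there.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file (missing header)") from None
    missing = [c for c in SURFACE_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in SURFACE_COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"{path}: bad columns (missing {missing or 'none'}, extra {extra or 'none'})"
        )
    if len(df) == 0:
        raise DegenerateGridError(f"{path}: no rectangles (header only)")
    values = np.empty((len(df), len(SURFACE_COLUMNS)))
    for j, col in enumerate(SURFACE_COLUMNS):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, row {i}"
                ) from None
    idx = values[:, 0]
    if not np.array_equal(idx, np.arange(len(df))):
        raise SchemaError(f"{path}: index column must be contiguous from 0")
    return SurfaceGrid(
        centers=values[:, 1:4],
        areas=values[:, 4],
        weights=values[:, 5],
    )


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; spacing goes in the affine and header."""
    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    data = np.asarray(vol.values)
    # count volumes are stored as int32 (exact round-trip), continuous as float64
    dtype = np.int32 if np.issubdtype(data.dtype, np.integer) else np.float64
    img = nib.Nifti1Image(data.astype(dtype), affine, dtype=dtype)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a 3-D NIfTI-1 volume; spacing is taken from the header."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ParameterError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise SchemaError(f"{path}: header lacks positive voxel spacing")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelVolume(values=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def write_result_json(result: PerfusionResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: cohort table missing columns {missing}")
    return df


def _build(cls, params: dict, name: str):
    try:
        return cls(**params)
    except TypeError as exc:
        raise SchemaError(f"config section {name!r}: {exc}") from None


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into spec objects.

    Recognised top-level sections: ``shape``, ``defect``, ``acquisition``,
    ``resolution``, ``cohort``, ``seed``. Unknown sections are rejected.
    Returns a dict holding the constructed spec objects (sections omitted
    from the file fall back to the dataclass defaults downstream).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {"shape", "defect", "acquisition", "resolution", "cohort", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config sections {sorted(unknown)}")
    out: dict = {}
    if "shape" in raw:
        out["shape"] = _build(LVShapeSpec, raw["shape"], "shape")
    if "defect" in raw:
        out["defect"] = _build(DefectSpec, raw["defect"], "defect")
    if "acquisition" in raw:
        acq = dict(raw["acquisition"])
        if "matrix" in acq and acq["matrix"] is not None:
            acq["matrix"] = tuple(int(v) for v in acq["matrix"])
        out["acquisition"] = _build(AcquisitionSpec, acq, "acquisition")
    if "resolution" in raw:
        out["resolution"] = _build(GridResolution, raw["resolution"], "resolution")
    if "cohort" in raw:
        cohort = dict(raw["cohort"])
        for key, cls in (("acquisition", AcquisitionSpec), ("shape", LVShapeSpec),
                         ("resolution", GridResolution)):
            if key in cohort:
                cohort[key] = _build(cls, cohort[key], f"cohort.{key}")
        if "locations" in cohort:
            cohort["locations"] = tuple(cohort["locations"])
        for key in ("alpha_range_deg", "severity_range", "extent_range_mm",
                    "rest_ratio_range"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        out["cohort"] = _build(CohortSpec, cohort, "cohort")
    if "seed" in raw:
        out["seed"] = int(raw["seed"])
    return out
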