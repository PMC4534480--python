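"""Perfusion-vector computation.

The core statistic of the package: with each surface rectangle carrying a
centre (x_i, y_i, z_i), an area A_i and an intensity weight W_i, the
weighted centroid is

    C = ( sum x_i A_i W_i / sum A_i W_i ,  ... y ... ,  ... z ... ).

With W_i = 1 this is the anatomical centroid C_A of the mid-myocardial
surface; with W_i set to the measured tracer intensity it is the perfusion
centre of gravity C_P. The perfusion vector is

    P = C_P - C_A ,

which points away from a perfusion defect, with a magnitude reflecting the
defect's severity and extent. Stress/rest comparisons report both the
difference of the two magnitudes and the magnitude of the vector difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import (
    DegenerateWeightsError,
    FrameMismatchError,
    ShapeMismatchError,
)
from .surface import SurfaceGrid

__all__ = [
    "Centroid",
    "PerfusionResult",
    "DifferenceResult",
    "weighted_centroid",
    "anatomical_centroid",
    "compute_perfusion_vector",
    "difference_metrics",
]

Phase = Literal["stress", "rest", "unspecified"]


@dataclass(frozen=True)
class Centroid:
    """A point in the cardiac frame, tagged anatomical or perfusion."""

    point: tuple[float, float, float]
    kind: Literal["anatomical", "perfusion"]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.point, dtype=float)


@dataclass(frozen=True)
class PerfusionResult:
    """Anatomical centroid, perfusion centre of gravity, and their difference."""

    c_anatomical: Centroid
    c_perfusion: Centroid
    vector: tuple[float, float, float]  # P = C_P - C_A, mm
    magnitude: float  # ||P||_2, mm
    phase: Phase = "unspecified"
    frame_name: str = "cardiac"

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=float)

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "C_A": list(self.c_anatomical.point),
            "C_P": list(self.c_perfusion.point),
            "P": list(self.vector),
            "magnitude": self.magnitude,
        }


@dataclass(frozen=True)
class DifferenceResult:
    """Stress/rest comparison metrics.

    ``magnitude_difference`` is |P_stress| - |P_rest| (may be negative);
    ``vector_difference_magnitude`` is ||P_stress - P_rest||.
    """

    magnitude_difference: float
    vector_difference_magnitude: float


def weighted_centroid(
    grid: SurfaceGrid,
    weights: np.ndarray | None = None,
    kind: Literal["anatomical", "perfusion"] = "perfusion",
) -> Centroid:
    """Area-and-intensity weighted centroid of the surface grid.

    Parameters
    ----------
    grid:
        Surface grid providing centres and areas (and, when ``weights`` is
        omitted, its own intensity weights).
    weights:
        Optional per-rectangle intensities overriding ``grid.weights``. Must
        be non-negative with at least one strictly positive A_i * W_i.
    """
    w = grid.weights if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(grid),):
        raise ShapeMismatchError(
            f"weights length {w.shape} does not match grid size {len(grid)}"
        )
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise DegenerateWeightsError("weights must be finite and non-negative")
    aw = grid.areas * w
    total = aw.sum()
    if total <= 0:
        raise DegenerateWeightsError("sum of A_i * W_i is zero; centroid undefined")
    point = (grid.centers * aw[:, None]).sum(axis=0) / total
    return Centroid(point=tuple(float(v) for v in point), kind=kind)


def anatomical_centroid(grid: SurfaceGrid) -> Centroid:
    """Geometric (unit-weight) centroid of the surface."""
    return weighted_centroid(grid, np.ones(len(grid)), kind="anatomical")


def compute_perfusion_vector(
    grid: SurfaceGrid,
    weights: np.ndarray | None = None,
    phase: Phase = "unspecified",
) -> PerfusionResult:
    """Compute P = C_P - C_A for a grid carrying measured intensities."""
    c_a = anatomical_centroid(grid)
    c_p = weighted_centroid(grid, weights, kind="perfusion")
    p = c_p.as_array() - c_a.as_array()
    return PerfusionResult(
        c_anatomical=c_a,
        c_perfusion=c_p,
        vector=tuple(float(v) for v in p),
        magnitude=float(np.linalg.norm(p)),
        phase=phase,
        frame_name=grid.frame.name,
    )


def difference_metrics(
    stress: PerfusionResult, rest: PerfusionResult
) -> DifferenceResult:
    """Stress/rest difference metrics; both results must share a frame."""
    if stress.frame_name != rest.frame_name:
        raise FrameMismatchError(
            f"frames differ: {stress.frame_name!r} vs {rest.frame_name!r}"
        )
    return DifferenceResult(
        magnitude_difference=float(stress.magnitude - rest.magnitude),
        vector_difference_magnitude=float(np.linalg.norm(stress.p - rest.p)),
    )
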