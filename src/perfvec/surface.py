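"""Parametric mid-myocardial left-ventricular surface.

The LV mid-wall is modelled as a truncated prolate ellipsoid: semi-axes
``mid_short_radius`` (both short axes) and ``mid_long_radius`` (long axis),
apex pole included, base left open at a truncation plane. The surface is
discretised into a regular grid of rectangles, each carrying an index ``i``,
a centre position ``(x_i, y_i, z_i)`` in mm, an area ``A_i`` in mm^2, and a
dimensionless intensity weight ``W_i``. This grid is the carrier for every
centroid computation in the package.

Cardiac frame convention (fixed, right-handed):

* +x : septal -> lateral
* +y : anterior -> inferior
* +z : basal -> apical

The circumferential angle theta is measured in the x-y plane from +x
(lateral), increasing toward +y (inferior); hence the wall centres sit at
theta = 0 (lateral), 90 (inferior), 180 (septal) and 270 degrees (anterior).
All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .errors import (
    DegenerateGridError,
    InvalidShapeError,
    InvalidTransformError,
)

__all__ = [
    "LVShapeSpec",
    "GridResolution",
    "CardiacFrame",
    "SurfaceGrid",
    "build_lv_surface",
    "transform_grid",
    "validate_grid",
    "solve_cavity_volume",
    "cavity_volume_ml",
    "analytic_surface_area",
]

#: Millimetres cubed per millilitre.
_MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class LVShapeSpec:
    """Geometry of the mid-myocardial ellipsoid.

    Parameters
    ----------
    mid_short_radius, mid_long_radius:
        Semi-axes of the mid-wall ellipsoid in mm (short axis applies to both
        x and y).
    base_truncation_fraction:
        Fraction ``f`` in (0, 1] of the long radius below the equator at
        which the base plane cuts the ellipsoid: the surface spans
        ``z in [-f * mid_long_radius, +mid_long_radius]`` with the apex at
        ``+mid_long_radius``.
    wall_thickness:
        Myocardial wall thickness in mm; used by the voxel rasteriser (the
        wall spans the mid surface +/- half of this) and by the cavity-volume
        solver.
    target_cavity_volume_ml:
        If set, :func:`build_lv_surface` rescales both radii so the
        end-diastolic cavity volume (interior of the endocardial ellipsoid
        above the base plane) equals this value. Default 148 mL, a standard
        male end-diastolic volume.
    """

    mid_short_radius: float = 25.0
    mid_long_radius: float = 45.0
    base_truncation_fraction: float = 0.35
    wall_thickness: float = 10.0
    target_cavity_volume_ml: float | None = 148.0

    def __post_init__(self) -> None:
        if not (self.mid_short_radius > 0 and self.mid_long_radius > 0):
            raise InvalidShapeError("radii must be positive")
        if not self.wall_thickness > 0:
            raise InvalidShapeError("wall_thickness must be positive")
        if not 0 < self.base_truncation_fraction <= 1:
            raise InvalidShapeError("base_truncation_fraction must lie in (0, 1]")
        if self.target_cavity_volume_ml is not None and self.target_cavity_volume_ml <= 0:
            raise InvalidShapeError("target_cavity_volume_ml must be positive")
        if self.wall_thickness >= 2 * min(self.mid_short_radius, self.mid_long_radius):
            raise InvalidShapeError("wall thicker than the ventricle")

    @property
    def base_plane_z(self) -> float:
        """z coordinate (mm) of the open base plane."""
        return -self.base_truncation_fraction * self.mid_long_radius

    @property
    def phi_base(self) -> float:
        """Polar angle (radians, from the apex pole) of the base plane."""
        return float(np.arccos(-self.base_truncation_fraction))


@dataclass(frozen=True)
class GridResolution:
    """Number of grid cells along the meridian and around the circumference."""

    n_longitudinal: int = 32
    n_circumferential: int = 64

    def __post_init__(self) -> None:
        if self.n_longitudinal < 4:
            raise InvalidShapeError("n_longitudinal must be >= 4")
        if self.n_circumferential < 8:
            raise InvalidShapeError("n_circumferential must be >= 8")


@dataclass(frozen=True)
class CardiacFrame:
    """Right-handed cardiac coordinate frame.

    +x septal->lateral, +y anterior->inferior, +z basal->apical; the origin
    is the centre of the mid-wall ellipsoid. Two results may only be
    combined when their frames compare equal.
    """

    name: str = "cardiac"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class SurfaceGrid:
    """Grid of surface rectangles with centres, areas and intensity weights.

    ``theta_deg``, ``arc_from_apex_mm`` and ``normals`` are parametric
    metadata attached at construction time (circumferential angle, meridional
    arc distance from the apex pole, outward unit normal). They survive rigid
    transforms but are not part of the CSV interchange format; grids read
    from CSV carry ``None`` there.
    """

    centers: np.ndarray  # (N, 3) mm
    areas: np.ndarray  # (N,) mm^2
    weights: np.ndarray  # (N,) dimensionless
    frame: CardiacFrame = field(default_factory=CardiacFrame)
    normals: np.ndarray | None = None  # (N, 3) unit vectors
    theta_deg: np.ndarray | None = None  # (N,) degrees in [0, 360)
    arc_from_apex_mm: np.ndarray | None = None  # (N,) mm
    dtheta_deg: float | None = None  # circumferential cell width
    darc_mm: np.ndarray | None = None  # (N,) meridional cell width
    shape: LVShapeSpec | None = None  # generating shape, if any

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 3:
            raise DegenerateGridError("centers must be an (N, 3) array")
        n = self.centers.shape[0]
        if self.areas.shape != (n,) or self.weights.shape != (n,):
            raise DegenerateGridError("areas/weights length must match centers")
        if n == 0:
            raise DegenerateGridError("surface grid is empty")

    def __len__(self) -> int:
        return self.centers.shape[0]

    @property
    def index(self) -> np.ndarray:
        return np.arange(len(self))

    def with_weights(self, weights: np.ndarray) -> "SurfaceGrid":
        """Return a copy of the grid carrying new intensity weights."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(self),):
            raise DegenerateGridError("weights length must match grid size")
        return replace(self, weights=w)


def _meridian_speed(phi: np.ndarray, a: float, c: float) -> np.ndarray:
    """|d/dphi (a sin phi, c cos phi)| — the meridional metric factor."""
    return np.sqrt((a * np.cos(phi)) ** 2 + (c * np.sin(phi)) ** 2)


def meridian_arc_table(shape: LVShapeSpec, n: int = 4097) -> tuple[np.ndarray, np.ndarray]:
    """Dense table of (phi, arc length from apex) along the meridian.

    Used to convert between the parametric polar angle and the physical arc
    distance from the apex pole, by linear interpolation.
    """
    a, c = shape.mid_short_radius, shape.mid_long_radius
    phi = np.linspace(0.0, shape.phi_base, n)
    speed = _meridian_speed(phi, a, c)
    s = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2 * np.diff(phi))])
    return phi, s


def cavity_volume_ml(shape: LVShapeSpec) -> float:
    """Cavity (endocardial) volume in mL, by closed form.

    The endocardial surface is the ellipsoid with semi-axes reduced by half
    the wall thickness, truncated at the base plane of the mid surface.
    """
    t2 = shape.wall_thickness / 2.0
    a_e = shape.mid_short_radius - t2
    c_e = shape.mid_long_radius - t2
    if a_e <= 0 or c_e <= 0:
        raise InvalidShapeError("wall thickness leaves no cavity")
    z0 = max(shape.base_plane_z, -c_e)
    # V = pi a_e^2 * integral_{z0}^{c_e} (1 - z^2/c_e^2) dz
    integral = (c_e - z0) - (c_e**3 - z0**3) / (3.0 * c_e**2)
    return float(np.pi * a_e**2 * integral) / _MM3_PER_ML


def solve_cavity_volume(shape: LVShapeSpec) -> LVShapeSpec:
    """Rescale both radii so the cavity volume hits the requested target.

    The aspect ratio, truncation fraction and wall thickness are kept fixed;
    a single scale factor on (short, long) radius is solved by bisection.
    Returns the shape unchanged when no target is set.
    """
    target = shape.target_cavity_volume_ml
    if target is None:
        return shape

    def volume_at(s: float) -> float:
        trial = replace(
            shape,
            mid_short_radius=shape.mid_short_radius * s,
            mid_long_radius=shape.mid_long_radius * s,
            target_cavity_volume_ml=None,
        )
        return cavity_volume_ml(trial) - target

    lo, hi = 0.3, 6.0
    # wall thickness bounds the smallest admissible scale
    min_scale = (shape.wall_thickness / 2 + 1e-6) / min(
        shape.mid_short_radius, shape.mid_long_radius
    )
    lo = max(lo, min_scale * 1.01)
    if volume_at(lo) > 0 or volume_at(hi) < 0:
        raise InvalidShapeError(
            f"cannot reach cavity volume {target} mL by scaling radii"
        )
    s = brentq(volume_at, lo, hi, xtol=1e-12)
    return replace(
        shape,
        mid_short_radius=shape.mid_short_radius * s,
        mid_long_radius=shape.mid_long_radius * s,
        target_cavity_volume_ml=None,
    )


def analytic_surface_area(shape: LVShapeSpec) -> float:
    """Surface area (mm^2) of the truncated ellipsoid by adaptive quadrature."""
    from scipy.integrate import quad

    a, c = shape.mid_short_radius, shape.mid_long_radius

    def integrand(phi: float) -> float:
        return 2 * np.pi * a * np.sin(phi) * float(_meridian_speed(np.asarray(phi), a, c))

    val, _ = quad(integrand, 0.0, shape.phi_base, limit=200)
    return float(val)


def build_lv_surface(
    shape: LVShapeSpec | None = None,
    res: GridResolution | None = None,
) -> SurfaceGrid:
    """Construct the mid-myocardial surface grid.

    The parametric domain ``phi in (0, phi_base], theta in [0, 2 pi)`` is
    split into ``n_longitudinal x n_circumferential`` cells; each rectangle
    sits at its cell centre with area equal to the local metric product
    (meridional arc spacing times circumferential arc spacing). Weights are
    initialised to 1. When the shape requests a target cavity volume the
    radii are first rescaled via :func:`solve_cavity_volume`.
    """
    shape = shape if shape is not None else LVShapeSpec()
    res = res if res is not None else GridResolution()
    shape = solve_cavity_volume(shape)

    a, c = shape.mid_short_radius, shape.mid_long_radius
    n_lon, n_cir = res.n_longitudinal, res.n_circumferential

    dphi = shape.phi_base / n_lon
    dtheta = 2 * np.pi / n_cir
    phi = (np.arange(n_lon) + 0.5) * dphi
    theta = (np.arange(n_cir) + 0.5) * dtheta

    phi_g, theta_g = np.meshgrid(phi, theta, indexing="ij")
    phi_f = phi_g.ravel()
    theta_f = theta_g.ravel()

    sin_phi, cos_phi = np.sin(phi_f), np.cos(phi_f)
    x = a * sin_phi * np.cos(theta_f)
    y = a * sin_phi * np.sin(theta_f)
    z = c * cos_phi
    centers = np.column_stack([x, y, z])

    areas = _meridian_speed(phi_f, a, c) * dphi * (a * sin_phi) * dtheta

    # outward normal of the ellipsoid: grad((x/a)^2 + (y/a)^2 + (z/c)^2)
    nx, ny, nz = x / a**2, y / a**2, z / c**2
    norm = np.sqrt(nx**2 + ny**2 + nz**2)
    normals = np.column_stack([nx / norm, ny / norm, nz / norm])

    # exact cell arc intervals: centres and widths from the band edges so
    # fractional-coverage defect masks tile the meridian without gaps
    phi_tab, s_tab = meridian_arc_table(shape)
    s_edges = np.interp(np.arange(n_lon + 1) * dphi, phi_tab, s_tab)
    band_centers = (s_edges[:-1] + s_edges[1:]) / 2.0
    band_widths = np.diff(s_edges)
    band_idx = np.repeat(np.arange(n_lon), n_cir)
    arc = band_centers[band_idx]
    darc = band_widths[band_idx]

    return SurfaceGrid(
        centers=centers,
        areas=areas,
        weights=np.ones(len(phi_f)),
        frame=CardiacFrame(),
        normals=normals,
        theta_deg=np.degrees(theta_f) % 360.0,
        arc_from_apex_mm=arc,
        dtheta_deg=float(np.degrees(dtheta)),
        darc_mm=darc,
        shape=shape,
    )


def transform_grid(
    grid: SurfaceGrid,
    rotation: np.ndarray,
    translation: np.ndarray | tuple[float, float, float],
) -> SurfaceGrid:
    """Apply a rigid motion to the grid centres (areas and weights unchanged).

    ``rotation`` must be orthonormal within 1e-8; normals are rotated
    alongside the centres so sampling stays consistent.
    """
    rot = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if rot.shape != (3, 3):
        raise InvalidTransformError("rotation must be a 3x3 matrix")
    if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8):
        raise InvalidTransformError("rotation is not orthonormal within 1e-8")
    new_centers = grid.centers @ rot.T + t
    new_normals = grid.normals @ rot.T if grid.normals is not None else None
    return replace(grid, centers=new_centers, normals=new_normals)


def exclude_basal(grid: SurfaceGrid, fraction: float) -> SurfaceGrid:
    """Drop the basal-most fraction of the surface (by meridional arc).

    Basal-rim delineation is the most fragile part of LV segmentation — a rim
    placed slightly outside the ventricle samples background and perturbs the
    perfusion vector. Excluding a basal fraction before the centroid
    computation is the corresponding sensitivity knob. ``fraction`` = 0
    returns the grid unchanged.
    """
    if not 0.0 <= fraction < 1.0:
        raise InvalidShapeError("basal exclusion fraction must lie in [0, 1)")
    if fraction == 0.0:
        return grid
    if grid.arc_from_apex_mm is None:
        raise DegenerateGridError(
            "grid lacks meridional arc metadata; build it with build_lv_surface"
        )
    span = float(grid.arc_from_apex_mm.max())
    keep = grid.arc_from_apex_mm <= (1.0 - fraction) * span
    if not np.any(keep):
        raise DegenerateGridError("basal exclusion removed every rectangle")
    return replace(
        grid,
        centers=grid.centers[keep],
        areas=grid.areas[keep],
        weights=grid.weights[keep],
        normals=None if grid.normals is None else grid.normals[keep],
        theta_deg=None if grid.theta_deg is None else grid.theta_deg[keep],
        arc_from_apex_mm=grid.arc_from_apex_mm[keep],
        darc_mm=None if grid.darc_mm is None else grid.darc_mm[keep],
    )


def validate_grid(grid: SurfaceGrid) -> list[str]:
    """Check the grid invariants; return one message per violation.

    Validation reports, it never raises: an empty list means every rectangle
    has positive area, finite centre coordinates and finite non-negative
    weight.
    """
    violations: list[str] = []
    for i in range(len(grid)):
        if not np.all(np.isfinite(grid.centers[i])):
            violations.append(f"rectangle {i}: non-finite position")
        if not np.isfinite(grid.areas[i]) or grid.areas[i] <= 0:
            violations.append(f"rectangle {i}: non-positive area")
        if not np.isfinite(grid.weights[i]) or grid.weights[i] < 0:
            violations.append(f"rectangle {i}: negative or non-finite weight")
    return violations
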