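"""Planar contour primitives and the Structure/ContourSlice data model.

All geometry lives in patient coordinates, in millimeters, with z the
axial axis (ascending toward superior).  A contour slice is a single
closed simple polygon on one axial plane; closure is implicit (the last
vertex differs from the first, and the edge last->first is implied).
Orientation is normalized counterclockwise as seen from superior (+z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    DegenerateContourError,
    MissingSpacingError,
    NonSimpleContourError,
    OriginOutsideError,
)

__all__ = [
    "ContourSlice",
    "Structure",
    "polygon_area",
    "polygon_centroid",
    "ray_crossings",
    "signed_area",
]

#: vertices closer than this (mm) are treated as coincident
_VERTEX_TOL = 1e-9
#: all vertices of one contour item must share z within this tolerance (mm)
COPLANARITY_TOL = 1e-3


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive = CCW)."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _as_vertex_array(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DegenerateContourError(
            f"vertices must be an (n, 2) array of planar points, got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class ContourSlice:
    """One closed axial polygon: z position plus ordered planar vertices (mm).

    Construction validates and normalizes the polygon: a duplicated
    closing vertex is dropped, orientation is forced counterclockwise,
    consecutive duplicate vertices and self-intersections are rejected.
    """

    z: float
    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = _as_vertex_array(self.vertices)
        # drop a duplicated closing vertex (reader convenience)
        if len(arr) >= 2 and np.linalg.norm(arr[-1] - arr[0]) < _VERTEX_TOL:
            arr = arr[:-1]
        if len(arr) < 3:
            raise DegenerateContourError(
                f"contour at z={self.z} has {len(arr)} distinct vertices; need >= 3"
            )
        seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        if np.any(seg < _VERTEX_TOL):
            raise DegenerateContourError(
                f"contour at z={self.z} has coincident consecutive vertices"
            )
        a = signed_area(arr)
        if abs(a) < _VERTEX_TOL:
            raise DegenerateContourError(f"contour at z={self.z} has zero area")
        if a < 0:  # normalize to CCW
            arr = arr[::-1].copy()
        if not _ShapelyPolygon(arr).is_valid:
            raise NonSimpleContourError(
                f"contour at z={self.z} is self-intersecting; "
                "non-simple contours are rejected, not repaired"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "z", float(self.z))
        object.__setattr__(self, "vertices", arr)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def shapely(self) -> _ShapelyPolygon:
        """The slice as a shapely polygon (for validity/containment checks)."""
        return _ShapelyPolygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "ContourSlice":
        return ContourSlice(self.z, self.vertices + np.array([dx, dy]))


def polygon_area(contour: ContourSlice) -> float:
    """Absolute shoelace area of the slice polygon, in mm^2.

    Always strictly positive for a valid :class:`ContourSlice`.
    """
    return abs(signed_area(contour.vertices))


def polygon_centroid(contour: ContourSlice) -> tuple[float, float]:
    """Area-weighted centroid of the polygon interior, in mm.

    Uses the standard shoelace centroid formula; this is the
    two-dimensional centroid of the contour in the transverse plane that
    seeds the iterative center refinement.
    """
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < _VERTEX_TOL:
        raise DegenerateContourError("zero-area polygon has no centroid")
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return (cx, cy)


def _ray_edge_hits(
    vertices: np.ndarray, origin: np.ndarray, angles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distances from ``origin`` to every edge crossing along each ray.

    Returns ``(t, valid)`` of shape (n_angles, n_edges): ``t`` is the ray
    parameter (distance, since directions are unit) and ``valid`` marks
    genuine crossings (t > 0, edge parameter s in [0, 1] up to rounding).
    A ray through a shared vertex may register on both adjacent edges
    with equal t; callers take the minimum or merge duplicates, so this
    is harmless — whereas a half-open interval can *lose* a vertex hit
    to rounding on both edges at once.
    """
    p = vertices
    q = np.roll(vertices, -1, axis=0)
    e = q - p  # (E, 2)
    w = p - origin  # (E, 2)
    d = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (A, 2)

    denom = d[:, 0:1] * e[None, :, 1] - d[:, 1:2] * e[None, :, 0]  # (A, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]) / denom
        s = (w[None, :, 0] * d[:, 1:2] - w[None, :, 1] * d[:, 0:1]) / denom
    valid = (np.abs(denom) > 1e-12) & (t > _VERTEX_TOL) & (s >= -1e-9) & (s <= 1.0 + 1e-9)
    return t, valid


def _point_strictly_inside(contour: ContourSlice, point) -> bool:
    from shapely.geometry import Point

    return contour.shapely().contains(Point(point[0], point[1]))


def ray_crossings(
    contour: ContourSlice, origin, angle: float
) -> np.ndarray:
    """Distances from an interior origin to every boundary crossing of a ray.

    Parameters
    ----------
    contour
        The slice polygon.
    origin
        Ray origin, strictly inside the polygon.
    angle
        Ray direction in radians (0 = +x axis).

    Returns
    -------
    numpy.ndarray
        Strictly positive crossing distances in ascending order.  Always
        non-empty for an interior origin; a convex polygon yields exactly
        one crossing, a concave one may yield an odd number > 1.
    """
    o = np.asarray(origin, dtype=float)
    if not _point_strictly_inside(contour, o):
        raise OriginOutsideError(
            f"ray origin {tuple(o)} is not strictly inside the contour at z={contour.z}"
        )
    t, valid = _ray_edge_hits(contour.vertices, o, np.atleast_1d(float(angle)))
    hits = np.sort(t[0][valid[0]])
    # merge numerically duplicate crossings (ray through a vertex)
    if len(hits) > 1:
        keep = np.concatenate([[True], np.diff(hits) > 1e-9])
        hits = hits[keep]
    return hits


@dataclass
class Structure:
    """A named, z-sorted collection of contour slices (GTV, STV, PTV, ring).

    At most one polygon is retained per axial position; when several
    disjoint polygons share a z (islands), the largest-area one is kept
    and a warning is emitted.  ``slice_spacing`` is the nominal axial
    spacing: the median of consecutive z differences, or the declared
    value for single-slice structures.
    """

    name: str
    slices: list[ContourSlice]
    declared_spacing: float | None = None

    def __post_init__(self) -> None:
        groups: dict[float, list[ContourSlice]] = {}
        for s in self.slices:
            key = round(s.z / COPLANARITY_TOL) * COPLANARITY_TOL
            groups.setdefault(key, []).append(s)
        kept: list[ContourSlice] = []
        for key in sorted(groups):
            cands = groups[key]
            if len(cands) > 1:
                warnings.warn(
                    f"structure {self.name!r}: {len(cands)} polygons at z={key:g}; "
                    "keeping the largest-area island",
                    stacklevel=2,
                )
                cands = [max(cands, key=polygon_area)]
            kept.append(cands[0])
        self.slices = kept

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def z_values(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    @property
    def z_min(self) -> float:
        return float(self.z_values.min())

    @property
    def z_max(self) -> float:
        return float(self.z_values.max())

    @property
    def slice_spacing(self) -> float:
        if len(self.slices) >= 2:
            return float(np.median(np.diff(self.z_values)))
        if self.declared_spacing is not None and self.declared_spacing > 0:
            return float(self.declared_spacing)
        raise MissingSpacingError(
            f"structure {self.name!r} has a single slice and no declared spacing"
        )
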