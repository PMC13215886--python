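"""Polar decomposition of a contour slice and iterative center refinement.

The core representation is a resampling of the slice boundary onto a
uniform angular grid about a chosen center: for each angle the radius is
the distance to the *nearest* boundary crossing along the ray.  Using the
nearest crossing guarantees that the polar region — and hence any
radially shrunken contour derived from it — is contained in the original
polygon even when the slice is not star-shaped about the center.

The center refinement loop emulates the manual habit of nudging a
too-eccentric seed point: starting from the area centroid, it compares
the longest and shortest radial distances and shifts the center a small
step toward the direction of maximum distance, repeating until the
center stabilizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .contour import (
    ContourSlice,
    _point_strictly_inside,
    _ray_edge_hits,
    polygon_centroid,
)
from .errors import DegenerateContourError, InvalidPolarError, OriginOutsideError

__all__ = ["PolarContour", "RefineParams", "to_polar", "from_polar", "refine_center"]

logger = logging.getLogger(__name__)


def _angle_grid(n_angles: int) -> np.ndarray:
    """Uniform angle grid on [0, 2pi), anchored at 0 = +x axis."""
    return np.arange(n_angles) * (2.0 * np.pi / n_angles)


@dataclass(frozen=True)
class PolarContour:
    """A slice re-expressed as radii on a uniform angle grid about a center.

    Attributes
    ----------
    center : (x, y) in mm.
    angles : strictly increasing, equally spaced grid in [0, 2pi).
    radii : one strictly positive radial distance (mm) per angle.
    z : axial position of the source slice (mm).
    """

    center: tuple[float, float]
    angles: np.ndarray = field(repr=False)
    radii: np.ndarray = field(repr=False)
    z: float = 0.0

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if angles.ndim != 1 or angles.shape != radii.shape or len(angles) < 3:
            raise InvalidPolarError("angles and radii must be equal-length 1-d arrays")
        steps = np.diff(angles)
        if np.any(steps <= 0) or np.ptp(steps) > 1e-9:
            raise InvalidPolarError("angles must be strictly increasing and equally spaced")
        if np.any(radii <= 0):
            raise InvalidPolarError("all polar radii must be strictly positive")
        angles.setflags(write=False)
        radii.setflags(write=False)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def r_max(self) -> float:
        return float(self.radii.max())

    @property
    def r_min(self) -> float:
        return float(self.radii.min())

    def scaled(self, ratio: float) -> "PolarContour":
        """Radially scale every radius by ``ratio`` about the same center."""
        return PolarContour(self.center, self.angles, self.radii * ratio, self.z)

    def expanded(self, margin: float) -> "PolarContour":
        """Add ``margin`` mm to every radius about the same center."""
        return PolarContour(self.center, self.angles, self.radii + margin, self.z)


@dataclass(frozen=True)
class RefineParams:
    """Parameters of the center-refinement loop.

    step_factor is the damping applied to the (r_max - r_min) disparity
    when shifting the center; tol (mm) is the shift magnitude below which
    the center is considered stable.
    """

    n_angles: int = 360
    step_factor: float = 0.1
    tol: float = 0.01
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.n_angles < 36:
            raise ValueError("n_angles must be >= 36")
        if not 0.0 < self.step_factor <= 0.5:
            raise ValueError("step_factor must be in (0, 0.5]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _nearest_radii(contour: ContourSlice, center: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Nearest-crossing radius for every angle (assumes interior center)."""
    t, valid = _ray_edge_hits(contour.vertices, center, angles)
    t = np.where(valid, t, np.inf)
    return t.min(axis=1)


def _disparity_probe(
    contour: ContourSlice, center: np.ndarray, angles: np.ndarray
) -> tuple[float, float, float]:
    """(r_max - r_min, r_max, angle of r_max) sampled on the uniform grid
    plus the exact vertex directions from ``center``.

    On a convex polygon the nearest-crossing radius attains its maxima at
    vertex directions, so augmenting the grid makes the sampled maximum
    exact; a uniform grid alone underestimates it once the center moves
    off the vertex rays, which would bias the refinement loop toward
    spurious descent steps on sharp-cornered contours.
    """
    vertex_angles = np.mod(
        np.arctan2(contour.vertices[:, 1] - center[1], contour.vertices[:, 0] - center[0]),
        2.0 * np.pi,
    )
    all_angles = np.concatenate([angles, vertex_angles])
    radii = _nearest_radii(contour, center, all_angles)
    i_max = int(np.argmax(radii))
    disparity = float(radii.max() - radii.min())
    return disparity, float(radii[i_max]), float(all_angles[i_max])


def to_polar(contour: ContourSlice, center, n_angles: int = 360) -> PolarContour:
    """Resample a slice boundary onto a uniform polar grid about ``center``.

    The radius at each angle is the distance to the nearest boundary
    crossing, so the polar region is always contained in the polygon.

    Raises
    ------
    OriginOutsideError
        If ``center`` is not strictly inside the polygon.
    """
    c = np.asarray(center, dtype=float)
    if not _point_strictly_inside(contour, c):
        raise OriginOutsideError(
            f"polar center {tuple(c)} is not strictly inside the contour at z={contour.z}"
        )
    angles = _angle_grid(n_angles)
    radii = _nearest_radii(contour, c, angles)
    if not np.all(np.isfinite(radii)):
        raise OriginOutsideError("ray casting found no boundary crossing; corrupt polygon?")
    return PolarContour((c[0], c[1]), angles, radii, z=contour.z)


def from_polar(polar: PolarContour) -> ContourSlice:
    """Reconstruct a contour slice from its polar representation.

    Vertex i = center + radii[i] * (cos angles[i], sin angles[i]); the
    result is star-shaped about the center and therefore simple, with
    counterclockwise orientation.
    """
    cx, cy = polar.center
    verts = np.stack(
        [cx + polar.radii * np.cos(polar.angles), cy + polar.radii * np.sin(polar.angles)],
        axis=1,
    )
    return ContourSlice(polar.z, verts)


def refine_center(contour: ContourSlice, params: RefineParams | None = None) -> tuple[float, float]:
    """Refine the polar center of a slice by damped radial-disparity descent.

    Starting from the area centroid, each iteration resamples the slice
    in polar form about the current center, finds the angle of the
    maximum radius, and shifts the center by step_factor*(r_max - r_min)
    along that direction.  A step that would leave the polygon, or that
    would increase the disparity (r_max - r_min), is halved until it
    improves; iteration stops when the accepted step falls below ``tol``
    or after ``max_iter`` iterations.  The returned center is strictly
    inside the polygon and never has a larger radial disparity than the
    starting centroid.

    Ties for the maximum radius break to the smallest angle index, so the
    result is deterministic.
    """
    if params is None:
        params = RefineParams()
    center = np.asarray(polygon_centroid(contour), dtype=float)
    angles = _angle_grid(params.n_angles)

    disparity, _, theta_max = _disparity_probe(contour, center, angles)
    if not np.isfinite(disparity):
        raise DegenerateContourError(
            f"ray casting failed from the centroid of the slice at z={contour.z:g}"
        )
    n_shifts = 0
    for _ in range(params.max_iter):
        step = params.step_factor * disparity
        if step < params.tol:
            break
        direction = np.array([np.cos(theta_max), np.sin(theta_max)])
        # halve the step until the candidate stays inside and improves
        accepted = False
        while step >= params.tol:
            cand = center + step * direction
            if _point_strictly_inside(contour, cand):
                cand_disp, _, cand_theta = _disparity_probe(contour, cand, angles)
                if cand_disp < disparity:
                    center, disparity, theta_max = cand, cand_disp, cand_theta
                    accepted = True
                    n_shifts += 1
                    break
            step *= 0.5
        if not accepted:
            break
    else:
        logger.debug("refine_center: max_iter=%d reached at z=%g", params.max_iter, contour.z)

    if not _point_strictly_inside(contour, center):
        raise DegenerateContourError("center refinement failed to stay inside the polygon")
    t, valid = _ray_edge_hits(contour.vertices, center, angles)
    t_near = np.where(valid, t, np.inf).min(axis=1)
    t_far = np.where(valid, t, -np.inf).max(axis=1)
    if np.any(t_far - t_near > 1e-6):  # boundary beyond the first exit point
        warnings.warn(
            f"slice at z={contour.z:g} is not star-shaped about the refined center; "
            "nearest-crossing radii keep the shrunken contour inside the polygon",
            stacklevel=2,
        )
    logger.debug("refine_center: %d shifts at z=%g", n_shifts, contour.z)
    return (float(center[0]), float(center[1]))
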