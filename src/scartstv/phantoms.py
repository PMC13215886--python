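"""Seeded synthetic tumor phantoms with known geometry.

Every pipeline stage is testable without clinical data: these generators
emit GTV-like structures whose centers, areas, volumes and axial extents
are known in closed form (sphere, ellipsoid, spindle), deliberately
asymmetric (egg: two merged spheres, whose area centroid and radial
center differ by construction), or irregular but reproducible (lobed:
random-phase cosine perturbations of a sphere, driven by a single
integer seed).

Randomness is confined to the lobed phantom; identical seeds produce
byte-identical structures.
"""

from __future__ import annotations

import math

import numpy as np

from .contour import ContourSlice, Structure
from .errors import InvalidPhantomError

__all__ = ["make_sphere", "make_ellipsoid", "make_spindle", "make_egg", "make_lobed"]


def _circle_vertices(cx: float, cy: float, r: float, n: int) -> np.ndarray:
    theta = np.arange(n) * (2.0 * np.pi / n)
    return np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1)


def _slice_positions(half_extent: float, spacing: float) -> np.ndarray:
    """z grid {-H+spacing, ..., H-spacing} strictly inside (-H, H)."""
    n = int(math.floor((half_extent - 1e-9) / spacing))
    return np.arange(-n, n + 1) * spacing


def make_sphere(radius: float, spacing: float, n_angles: int = 360) -> Structure:
    """Sphere of given radius (mm) sliced axially every ``spacing`` mm.

    Slices are circles r(z) = sqrt(R^2 - z^2) at z in
    {-R+spacing, ..., R-spacing}; the analytic volume is 4/3 pi R^3.
    """
    if radius <= spacing:
        raise InvalidPhantomError(
            f"sphere radius {radius} mm must exceed slice spacing {spacing} mm"
        )
    slices = [
        ContourSlice(z, _circle_vertices(0.0, 0.0, math.sqrt(radius**2 - z**2), n_angles))
        for z in _slice_positions(radius, spacing)
    ]
    return Structure(f"GTV_sphere_R{radius:g}", slices, declared_spacing=spacing)


def make_ellipsoid(a: float, b: float, c: float, spacing: float, n_angles: int = 360) -> Structure:
    """Axis-aligned ellipsoid with semi-axes a, b (in-plane) and c (axial)."""
    if min(a, b, c) <= 0 or c <= spacing:
        raise InvalidPhantomError("ellipsoid semi-axes must be positive with c > spacing")
    theta = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    slices = []
    for z in _slice_positions(c, spacing):
        f = math.sqrt(1.0 - (z / c) ** 2)
        verts = np.stack([a * f * np.cos(theta), b * f * np.sin(theta)], axis=1)
        slices.append(ContourSlice(z, verts))
    return Structure(f"GTV_ellipsoid_{a:g}x{b:g}x{c:g}", slices, declared_spacing=spacing)


def make_spindle(
    radius: float, half_length: float, spacing: float, pinch: float = 1.5, n_angles: int = 360
) -> Structure:
    """Spindle: an ellipsoid-like solid with pinched (tapered) ends.

    The slice radius profile is r(z) = radius * (1 - (z/half_length)^2)^pinch;
    pinch = 0.5 recovers a prolate spheroid, larger values taper the ends
    more sharply, mirroring the spindle-shaped target geometry of the
    SCART treatment volume.
    """
    if radius <= 0 or half_length <= spacing:
        raise InvalidPhantomError("spindle needs radius > 0 and half_length > spacing")
    if pinch < 0.5:
        raise InvalidPhantomError("pinch < 0.5 would bulge, not pinch; use >= 0.5")
    slices = []
    for z in _slice_positions(half_length, spacing):
        r = radius * (1.0 - (z / half_length) ** 2) ** pinch
        slices.append(ContourSlice(z, _circle_vertices(0.0, 0.0, r, n_angles)))
    return Structure(f"GTV_spindle_R{radius:g}", slices, declared_spacing=spacing)


def _hull_of_two_circles(
    c1: np.ndarray, r1: float, c2: np.ndarray, r2: float, n: int
) -> np.ndarray:
    """Convex hull boundary of two overlapping circles, sampled CCW.

    Composed of the major arc of each circle between the external
    tangent points, joined by the two tangent segments; when one circle
    contains the other, the hull is just the larger circle.
    """
    d = float(np.linalg.norm(c2 - c1))
    if d + min(r1, r2) <= max(r1, r2) + 1e-12:  # one circle inside the other
        big_c, big_r = (c1, r1) if r1 >= r2 else (c2, r2)
        return _circle_vertices(big_c[0], big_c[1], big_r, n)
    if d >= r1 + r2:
        raise InvalidPhantomError("circles do not overlap; egg cross-section is disconnected")
    phi = math.atan2(c2[1] - c1[1], c2[0] - c1[0])
    # external tangent lines touch each circle at +/- beta from the center line
    beta = math.acos((r1 - r2) / d)
    n1 = max(int(round(n * (2 * math.pi - 2 * beta) / (2 * math.pi))), 2)
    n2 = max(n - n1, 2)
    a1 = phi + beta + (2 * math.pi - 2 * beta) * np.linspace(0.0, 1.0, n1, endpoint=True)
    a2 = phi - beta + 2 * beta * np.linspace(0.0, 1.0, n2, endpoint=True)
    arc1 = np.stack([c1[0] + r1 * np.cos(a1), c1[1] + r1 * np.sin(a1)], axis=1)
    arc2 = np.stack([c2[0] + r2 * np.cos(a2), c2[1] + r2 * np.sin(a2)], axis=1)
    return np.vstack([arc1, arc2])


def make_egg(
    r_big: float, r_small: float, offset: float, spacing: float, n_angles: int = 360
) -> Structure:
    """Asymmetric "egg": convex hull of two merged spheres.

    The big sphere sits at the origin, the small one ``offset`` mm away
    along +x; each axial slice is the convex hull of the two spheres'
    circular cross-sections.  The area centroid and the refined radial
    center differ by construction, which exercises the center-shifting
    loop.  With offset = 0 the phantom degenerates to a sphere of radius
    max(r_big, r_small).
    """
    if min(r_big, r_small) <= 0:
        raise InvalidPhantomError("egg radii must be positive")
    if offset >= r_big + r_small:
        raise InvalidPhantomError(
            f"offset {offset} mm >= r_big + r_small = {r_big + r_small} mm: spheres disjoint"
        )
    half = max(r_big, r_small)
    c1 = np.array([0.0, 0.0])
    c2 = np.array([offset, 0.0])
    slices = []
    for z in _slice_positions(half, spacing):
        rr1 = r_big**2 - z**2
        rr2 = r_small**2 - z**2
        if rr1 <= 0 and rr2 <= 0:
            continue
        if rr2 <= 0:
            verts = _circle_vertices(0.0, 0.0, math.sqrt(rr1), n_angles)
        elif rr1 <= 0:
            verts = _circle_vertices(offset, 0.0, math.sqrt(rr2), n_angles)
        else:
            verts = _hull_of_two_circles(c1, math.sqrt(rr1), c2, math.sqrt(rr2), n_angles)
        slices.append(ContourSlice(z, verts))
    if len(slices) < 1:
        raise InvalidPhantomError("egg phantom produced no slices; check radii vs spacing")
    return Structure(f"GTV_egg_{r_big:g}_{r_small:g}", slices, declared_spacing=spacing)


def make_lobed(
    base_radius: float,
    n_lobes: int,
    amplitude: float,
    spacing: float,
    seed: int,
    n_angles: int = 360,
) -> Structure:
    """Irregular lobed phantom: sphere with random-phase cosine lobes.

    Each slice radius is r(theta, z) = sqrt(R^2 - z^2) * (1 + A * sum_k
    cos(k*theta + phi_k)) for lobe orders k = 1..n_lobes with phases
    phi_k drawn once per structure from a seeded generator, so radii stay
    within the bound [r(z)*(1 - A*n), r(z)*(1 + A*n)] and the same seed
    reproduces the structure exactly.  Slices are star-shaped about the
    z axis by construction (all radii positive requires A*n_lobes < 1).
    """
    if not 0.0 <= amplitude < 1.0:
        raise InvalidPhantomError(f"amplitude must be in [0, 1), got {amplitude}")
    if n_lobes < 1:
        raise InvalidPhantomError("n_lobes must be >= 1")
    if amplitude * n_lobes >= 1.0:
        raise InvalidPhantomError(
            f"amplitude*n_lobes = {amplitude * n_lobes:g} >= 1 allows non-positive radii"
        )
    if base_radius <= spacing:
        raise InvalidPhantomError("base_radius must exceed slice spacing")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_lobes)
    theta = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    orders = np.arange(1, n_lobes + 1)
    modulation = 1.0 + amplitude * np.sum(
        np.cos(orders[:, None] * theta[None, :] + phases[:, None]), axis=0
    )
    slices = []
    for z in _slice_positions(base_radius, spacing):
        r = math.sqrt(base_radius**2 - z**2) * modulation
        verts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        slices.append(ContourSlice(z, verts))
    return Structure(f"GTV_lobed_seed{seed}", slices, declared_spacing=spacing)
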