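"""Pure 3D geometry kernel for annular contour morphometry.

An annulus contour is an ordered, closed ring of 3D points (mm). This
module provides the primitives the TAPSE-volume measurement is built
from: total-least-squares plane fitting, orthogonal projection onto a
plane, planar polygon area via the shoelace formula in a deterministic
in-plane basis, the vertex centroid, and point-to-plane distance.

All functions accept ``(n, 3)`` float arrays. Coordinates are in mm;
areas in mm². The plane-normal sign is fixed by a reproducible
convention (non-negative z component, ties broken toward +y then +x) so
that repeated runs produce identical output; all distances are absolute
values, so the sign convention never propagates into results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "Plane",
    "as_contour",
    "fit_plane",
    "project_to_plane",
    "polygon_area",
    "centroid",
    "point_plane_distance",
]

_UNIT_TOL = 1e-12          # unit-norm tolerance for plane normals
_COPLANAR_TOL = 1e-8       # mm; far below the 0.5 mm CT slice thickness
_DUPLICATE_TOL = 1e-9      # mm; consecutive vertices closer than this are duplicates


class DegenerateGeometryError(ValueError):
    """A contour is too degenerate for the requested operation."""


@dataclass(frozen=True)
class Plane:
    """A plane given by a unit normal and a point lying on it.

    Parameters
    ----------
    normal : (3,) array-like
        Plane normal; normalised on construction. Must be nonzero.
    point : (3,) array-like
        Any point on the plane (mm). ``fit_plane`` uses the contour
        centroid.
    """

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float).reshape(3)
        p = np.asarray(self.point, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < _UNIT_TOL:
            raise DegenerateGeometryError("plane normal must be a nonzero finite vector")
        if abs(norm - 1.0) > _UNIT_TOL:
            n = n / norm
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "point", p)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed orthogonal distance of one or more points (mm)."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.point) @ self.normal


def as_contour(points, label: str = "contour") -> np.ndarray:
    """Validate an ordered closed contour and return it as an (n, 3) array.

    Enforces: at least 3 vertices, finite coordinates, and no two
    consecutive vertices (including last-to-first) closer than 1e-9 mm.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateGeometryError(f"{label}: expected (n, 3) point array, got shape {pts.shape}")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(f"{label}: need at least 3 vertices, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometryError(f"{label}: contour contains non-finite coordinates")
    closed = np.vstack([pts, pts[:1]])
    steps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(steps < _DUPLICATE_TOL):
        i = int(np.argmax(steps < _DUPLICATE_TOL))
        raise DegenerateGeometryError(f"{label}: consecutive duplicate vertices at index {i}")
    return pts


def _orient_normal(n: np.ndarray) -> np.ndarray:
    # Non-negative dot with +z; ties broken toward +y, then +x.
    for axis in (2, 1, 0):
        if n[axis] > _UNIT_TOL:
            return n
        if n[axis] < -_UNIT_TOL:
            return -n
    return n


def fit_plane(points, label: str = "contour") -> Plane:
    """Total-least-squares best-fit plane of a 3D point set.

    Minimises the sum of squared orthogonal point-to-plane distances;
    the solution is the singular vector of the centred point matrix with
    the smallest singular value. The plane's reference point is the
    arithmetic centroid of the input.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 points are given or the points are collinear
        (the plane is then not unique); the message names `label`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError(f"{label}: plane fit needs >=3 points with 3 coordinates")
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometryError(f"{label}: non-finite coordinates")
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c, full_matrices=False)
    # s[1] ~ 0 means all points lie on a line: every plane through it is a fit.
    if s[1] <= max(s[0], 1.0) * 1e-10:
        raise DegenerateGeometryError(f"{label}: points are collinear; best-fit plane undefined")
    return Plane(_orient_normal(vt[2]), c)


def project_to_plane(points, plane: Plane) -> np.ndarray:
    """Orthogonal projection of points onto a plane.

    Idempotent; output satisfies ``(v - plane.point) . normal == 0`` to
    machine precision.
    """
    pts = np.asarray(points, dtype=float)
    offsets = plane.signed_distance(pts)
    return pts - np.multiply.outer(offsets, plane.normal)


def _in_plane_basis(plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    # First basis vector: normalised in-plane projection of the global
    # axis least aligned with the normal; second completes a RH frame.
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(plane.normal)))] = 1.0
    u = axis - (axis @ plane.normal) * plane.normal
    u /= np.linalg.norm(u)
    w = np.cross(plane.normal, u)
    return u, w


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _within_bbox(s1: np.ndarray, s2: np.ndarray, p: np.ndarray) -> np.ndarray:
    lo = np.minimum(s1, s2)
    hi = np.maximum(s1, s2)
    return np.all((lo <= p) & (p <= hi), axis=-1)


def _is_simple(xy: np.ndarray) -> bool:
    """Check a closed 2D polygon for self-intersection (O(n²) pairwise)."""
    n = len(xy)
    if n < 4:
        return True
    a1 = xy
    a2 = np.roll(xy, -1, axis=0)
    i, j = np.triu_indices(n, k=2)
    wrap = (i == 0) & (j == n - 1)  # first and last edges are adjacent
    i, j = i[~wrap], j[~wrap]
    p1, p2 = a1[i], a2[i]
    q1, q2 = a1[j], a2[j]
    d1 = _cross2(q2 - q1, p1 - q1)
    d2 = _cross2(q2 - q1, p2 - q1)
    d3 = _cross2(p2 - p1, q1 - p1)
    d4 = _cross2(p2 - p1, q2 - p1)
    if np.any((d1 * d2 < 0) & (d3 * d4 < 0)):
        return False
    touch = (
        ((d1 == 0) & _within_bbox(q1, q2, p1))
        | ((d2 == 0) & _within_bbox(q1, q2, p2))
        | ((d3 == 0) & _within_bbox(p1, p2, q1))
        | ((d4 == 0) & _within_bbox(p1, p2, q2))
    )
    return not np.any(touch)


def polygon_area(points, plane: Plane, check_simple: bool = True, label: str = "contour") -> float:
    """Area (mm²) of a planar closed polygon via the shoelace formula.

    The vertices must be coplanar with `plane` (within 1e-8 mm; project
    them first if needed). They are expressed in a deterministic
    orthonormal in-plane basis and the 2D shoelace formula is applied;
    the absolute value is returned, so the result does not depend on
    traversal direction, cyclic reindexing, or the basis choice.

    Raises
    ------
    DegenerateGeometryError
        If the polygon is not coplanar with the plane or (when
        `check_simple`) self-intersects.
    """
    pts = as_contour(points, label=label)
    offsets = plane.signed_distance(pts)
    worst = float(np.max(np.abs(offsets)))
    if worst > _COPLANAR_TOL:
        raise DegenerateGeometryError(
            f"{label}: vertices deviate from the plane by up to {worst:.3g} mm "
            f"(tolerance {_COPLANAR_TOL:g}); project first"
        )
    u, w = _in_plane_basis(plane)
    rel = pts - plane.point
    xy = np.column_stack([rel @ u, rel @ w])
    if check_simple and not _is_simple(xy):
        raise DegenerateGeometryError(f"{label}: polygon is self-intersecting")
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def centroid(points) -> np.ndarray:
    """Arithmetic mean of the vertices (the ring's 'center of mass').

    The contour vertices are treated as equally weighted samples of the
    ring; no arc-length or area weighting is applied.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
        raise DegenerateGeometryError("centroid needs at least one 3D point")
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometryError("centroid: non-finite coordinates")
    return pts.mean(axis=0)


def point_plane_distance(p, plane: Plane) -> float:
    """Absolute orthogonal distance (mm) from a point to a plane."""
    return float(abs(plane.signed_distance(np.asarray(p, dtype=float).reshape(3))))
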