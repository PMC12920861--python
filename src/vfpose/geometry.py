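"""Coordinate geometry for vocal-fold pose estimation.

All coordinates are 0-based pixel-center image coordinates: +x rightward,
+y downward. The anterior glottic angle (AGA) is the angle at the anterior
commissure A between the two vocal-fold free borders, i.e. between the
vectors A->LV and A->RV, reported as an unsigned magnitude in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Keypoint",
    "KeypointTriplet",
    "DegenerateGeometryError",
    "compute_aga",
    "triangle_mask",
    "min_enclosing_triangle",
    "label_triangle_vertices",
    "triplet_from_mask",
    "shoelace_area",
]


class DegenerateGeometryError(ValueError):
    """Raised when geometry is degenerate (zero-length vectors, collinear
    or empty point sets) and the requested quantity is undefined."""


@dataclass(frozen=True)
class Keypoint:
    """A single landmark with a COCO-style visibility flag.

    visibility: 0 = not present, 1 = present but occluded, 2 = visible.
    """

    x: float
    y: float
    visibility: int = 2

    def __post_init__(self) -> None:
        if self.visibility not in (0, 1, 2):
            raise ValueError(f"visibility must be 0, 1 or 2, got {self.visibility}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"keypoint coordinates must be finite, got ({self.x}, {self.y})")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class KeypointTriplet:
    """The three glottal landmarks: posterior angles of the left (LV) and
    right (RV) vocal fold and the anterior commissure (A)."""

    LV: Keypoint
    RV: Keypoint
    A: Keypoint

    def as_array(self) -> np.ndarray:
        """(3, 2) array in channel order LV, RV, A."""
        return np.stack([self.LV.xy, self.RV.xy, self.A.xy])

    def scaled(self, sx: float, sy: float) -> "KeypointTriplet":
        return KeypointTriplet(
            LV=Keypoint(self.LV.x * sx, self.LV.y * sy, self.LV.visibility),
            RV=Keypoint(self.RV.x * sx, self.RV.y * sy, self.RV.visibility),
            A=Keypoint(self.A.x * sx, self.A.y * sy, self.A.visibility),
        )


def compute_aga(triplet: KeypointTriplet) -> float:
    """Anterior glottic angle in degrees.

    The angle between the vector from A to LV and the vector from A to RV,
    computed with the two-argument arctangent of (cross, dot) and returned
    as an absolute value in [0, 180].

    Raises
    ------
    DegenerateGeometryError
        If A coincides with LV or RV (a zero-length border vector).
    """
    u = triplet.LV.xy - triplet.A.xy
    v = triplet.RV.xy - triplet.A.xy
    nu = float(np.hypot(*u))
    nv = float(np.hypot(*v))
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("AGA undefined: A coincides with LV or RV")
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return abs(math.degrees(math.atan2(cross, dot)))


def _cross2(u, v) -> float:
    """z-component of the 2D cross product (np.cross on 2-vectors is
    deprecated in numpy 2)."""
    return float(u[0] * v[1] - u[1] * v[0])


def shoelace_area(points: np.ndarray) -> float:
    """Unsigned polygon area from vertex coordinates, (n, 2)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _triplet_vertices(triplet: KeypointTriplet) -> np.ndarray:
    return np.stack([triplet.LV.xy, triplet.A.xy, triplet.RV.xy])


def triangle_mask(triplet: KeypointTriplet, height: int, width: int) -> np.ndarray:
    """Rasterize the glottal triangle (LV, A, RV) to a binary mask.

    A pixel is foreground iff its center lies inside the triangle or on its
    boundary (half-plane sign test, exact up to floating point).

    Returns an (height, width) uint8 array of {0, 1}.

    Raises
    ------
    DegenerateGeometryError
        If the three keypoints are collinear (zero-area glottis).
    """
    if height <= 0 or width <= 0:
        raise ValueError("mask dimensions must be positive")
    verts = _triplet_vertices(triplet)
    if shoelace_area(verts) == 0.0:
        raise DegenerateGeometryError("collinear keypoints: zero-area glottal triangle")

    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    X, Y = np.meshgrid(xs, ys)

    inside = np.ones((height, width), dtype=bool)
    # orientation sign of the triangle fixes which side of each edge is "in"
    orient = np.sign(_cross2(verts[1] - verts[0], verts[2] - verts[0]))
    for i in range(3):
        a, b = verts[i], verts[(i + 1) % 3]
        s = (b[0] - a[0]) * (Y - a[1]) - (b[1] - a[1]) * (X - a[0])
        inside &= orient * s >= -1e-9
    return inside.astype(np.uint8)


def _convex_hull(points: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex hull (Andrew's monotone chain).

    Works directly on integer/float points; returns (h, 2) float array.
    scipy's ConvexHull raises on flat inputs, and for pixel grids the
    monotone chain is simpler to keep exact.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 distinct points for a hull")
    # lexicographic sort by (x, y)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def half(seq):
        out: list[np.ndarray] = []
        for p in seq:
            while len(out) >= 2 and _cross2(out[-1] - out[-2], p - out[-2]) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(pts[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise DegenerateGeometryError("points are collinear: no 2D hull")
    return hull


def _line_intersection(p1, d1, p2, d2):
    """Intersection of lines p1 + t*d1 and p2 + s*d2, or None if parallel."""
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-12:
        return None
    t = ((p2[0] - p1[0]) * d2[1] - (p2[1] - p1[1]) * d2[0]) / denom
    return p1 + t * d1


def min_enclosing_triangle(mask: np.ndarray) -> np.ndarray:
    """Vertices of the minimum-area triangle enclosing all foreground pixels.

    The convex hull of the foreground pixel centers is computed first; the
    search then enumerates triangles whose three sides are flush with hull
    edges (each side's supporting line contains a hull edge) and returns the
    smallest one that contains the whole hull. Hulls of rasterized regions
    are small, so the cubic enumeration is cheap.

    Returns an unlabeled (3, 2) float array of vertices.

    Raises
    ------
    DegenerateGeometryError
        Empty mask, fewer than 3 foreground pixels, or collinear foreground —
        the prediction is undecodable and should be recorded as missing.
    """
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if len(xs) < 3:
        raise DegenerateGeometryError("mask has fewer than 3 foreground pixels")
    pts = np.column_stack([xs, ys]).astype(float)
    hull = _convex_hull(pts)  # raises on collinear foreground
    return _min_triangle_flush(hull)


def _min_triangle_flush(hull: np.ndarray) -> np.ndarray:
    """Smallest flush-side enclosing triangle of a CCW convex polygon."""
    h = len(hull)
    edges = [(hull[i], hull[(i + 1) % h] - hull[i]) for i in range(h)]
    if h == 3:
        return hull.copy()

    best_area = math.inf
    best = None
    for i in range(h):
        for j in range(i + 1, h):
            for k in range(j + 1, h):
                tri = _triangle_from_lines(edges[i], edges[j], edges[k])
                if tri is None:
                    continue
                if not _contains_all(tri, hull):
                    continue
                area = shoelace_area(tri)
                if area < best_area - 1e-12:
                    best_area = area
                    best = tri
    if best is None:
        # fall back: axis-aligned bounding triangle (cannot normally happen
        # for a bounded hull, but keeps the decoder total)
        xmin, ymin = hull.min(axis=0)
        xmax, ymax = hull.max(axis=0)
        w, hgt = xmax - xmin, ymax - ymin
        best = np.array(
            [[xmin - w, ymax], [xmax + w, ymax], [(xmin + xmax) / 2, ymin - hgt]]
        )
    return best


def _triangle_from_lines(e1, e2, e3):
    ps = (e1[0], e2[0], e3[0])
    ds = (e1[1], e2[1], e3[1])
    v1 = _line_intersection(ps[0], ds[0], ps[1], ds[1])
    v2 = _line_intersection(ps[1], ds[1], ps[2], ds[2])
    v3 = _line_intersection(ps[2], ds[2], ps[0], ds[0])
    if v1 is None or v2 is None or v3 is None:
        return None
    tri = np.stack([v1, v2, v3])
    if shoelace_area(tri) < 1e-9:
        return None
    return tri


def _contains_all(tri: np.ndarray, pts: np.ndarray, tol: float = 1e-7) -> bool:
    orient = np.sign(_cross2(tri[1] - tri[0], tri[2] - tri[0]))
    if orient == 0:
        return False
    for i in range(3):
        a, b = tri[i], tri[(i + 1) % 3]
        s = (b[0] - a[0]) * (pts[:, 1] - a[1]) - (b[1] - a[1]) * (pts[:, 0] - a[0])
        if np.any(orient * s < -tol):
            return False
    return True


def _interior_angles(verts: np.ndarray) -> np.ndarray:
    angles = np.empty(3)
    for i in range(3):
        u = verts[(i + 1) % 3] - verts[i]
        v = verts[(i + 2) % 3] - verts[i]
        cross = u[0] * v[1] - u[1] * v[0]
        dot = u[0] * v[0] + u[1] * v[1]
        angles[i] = abs(math.atan2(cross, dot))
    return angles


def label_triangle_vertices(vertices: Sequence[Sequence[float]]) -> KeypointTriplet:
    """Assign LV / RV / A identities to three unlabeled triangle vertices.

    The anterior commissure A is the apex of the elongated glottal triangle,
    taken as the vertex with the smallest interior angle. The remaining two
    are assigned so that the cross product (LV-A) x (RV-A), in image
    coordinates (y down), is positive — under the endoscopic convention the
    anatomical left fold appears on the image right.

    Ties (e.g. an equilateral triangle) are broken deterministically: among
    tied smallest-angle vertices, the one with the lowest y, then lowest x,
    becomes A.

    Raises
    ------
    DegenerateGeometryError
        If the vertices are collinear.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.shape != (3, 2):
        raise ValueError("expected exactly three 2D vertices")
    if shoelace_area(verts) < 1e-12:
        raise DegenerateGeometryError("collinear vertices cannot be labeled")

    angles = _interior_angles(verts)
    amin = angles.min()
    tied = np.where(np.isclose(angles, amin, atol=1e-9))[0]
    if len(tied) > 1:
        # lowest y, then lowest x
        sub = verts[tied]
        order = np.lexsort((sub[:, 0], sub[:, 1]))
        apex = int(tied[order[0]])
    else:
        apex = int(tied[0])

    a = verts[apex]
    p, q = verts[(apex + 1) % 3], verts[(apex + 2) % 3]
    u, v = p - a, q - a
    if u[0] * v[1] - u[1] * v[0] > 0:
        lv, rv = p, q
    else:
        lv, rv = q, p
    return KeypointTriplet(
        LV=Keypoint(float(lv[0]), float(lv[1])),
        RV=Keypoint(float(rv[0]), float(rv[1])),
        A=Keypoint(float(a[0]), float(a[1])),
    )


def triplet_from_mask(mask: np.ndarray) -> KeypointTriplet:
    """Decode a predicted glottal mask into a labeled keypoint triplet.

    Convenience composition: minimum enclosing triangle, then vertex
    labeling. Raises DegenerateGeometryError on undecodable masks.
    """
    return label_triangle_vertices(min_enclosing_triangle(mask))
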