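"""Geometric primitives: polygon rasterization, enclosing and inscribed
circles, and common external tangents of two circles.

All point coordinates are (x, y) with x = column and y = row.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .types import EnclosingCircle, InscribedCircle, TangentConstruction, as_binary_mask

__all__ = [
    "rasterize_polygon",
    "min_enclosing_circle",
    "min_enclosing_circle_points",
    "max_inscribed_circle",
    "external_tangent_quad",
    "TangentDegenerateError",
]


class TangentDegenerateError(ValueError):
    """Raised when two circles admit no common external tangents
    (center distance <= |r1 - r2|, one circle inside the other's span)."""


# ---------------------------------------------------------------------------
# rasterization


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a binary mask.

    A pixel (row, col) is set iff the point (x=col, y=row) lies inside or on
    the boundary of the polygon (even-odd rule, boundary inclusive).
    Degenerate (zero-area) polygons yield an empty mask.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    poly = Polygon(verts)
    if poly.area == 0:
        return mask
    # restrict the point-in-polygon test to the bounding box
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(w - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(h - 1, int(np.ceil(maxy)))
    if c0 > c1 or r0 > r1:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.intersects_xy(poly, cols.ravel().astype(float), rows.ravel().astype(float))
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rows.shape).astype(np.uint8)
    return mask


# ---------------------------------------------------------------------------
# minimum enclosing circle (Welzl)


def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.linalg.norm(p - c))


def _circle_three(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, float] | None:
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None  # collinear
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.linalg.norm(p - c))


def _in_circle(pt: np.ndarray, c: np.ndarray, r: float, eps: float = 1e-9) -> bool:
    return float(np.linalg.norm(pt - c)) <= r + eps


def _welzl(points: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Move-to-front Welzl on a (shuffled) point set; expected linear time."""
    pts = points[rng.permutation(len(points))]
    c, r = pts[0].copy(), 0.0
    for i in range(1, len(pts)):
        if _in_circle(pts[i], c, r):
            continue
        c, r = pts[i].copy(), 0.0
        for j in range(i):
            if _in_circle(pts[j], c, r):
                continue
            c, r = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(pts[k], c, r):
                    continue
                res = _circle_three(pts[i], pts[j], pts[k])
                if res is None:
                    # collinear support: take the farthest pair
                    cand = max(
                        (_circle_two(pts[i], pts[k]), _circle_two(pts[j], pts[k])),
                        key=lambda cr: cr[1],
                    )
                    c, r = cand
                else:
                    c, r = res
    return c, r


def min_enclosing_circle(mask: np.ndarray) -> EnclosingCircle:
    """Smallest circle containing all foreground pixel centers of a mask.

    Pixel centers are taken at integer (x=col, y=row) coordinates.
    """
    m = as_binary_mask(mask)
    rows, cols = np.nonzero(m)
    return min_enclosing_circle_points(np.column_stack([cols, rows]).astype(float))


def min_enclosing_circle_points(points: np.ndarray) -> EnclosingCircle:
    """Smallest circle containing an (n, 2) set of (x, y) points."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or (len(points) and points.shape[1] != 2):
        raise ValueError("expected an (n, 2) point array")
    if len(points) == 0:
        raise ValueError("empty mask: no enclosing circle")
    if len(points) == 1:
        return EnclosingCircle(center=(float(points[0, 0]), float(points[0, 1])), radius=0.0)
    # the enclosing circle is determined by convex-hull points only
    if len(points) > 16:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # collinear input: Welzl handles it directly
    rng = np.random.default_rng(0)  # internal shuffle only; result is unique
    c, r = _welzl(points, rng)
    return EnclosingCircle(center=(float(c[0]), float(c[1])), radius=float(r))


# ---------------------------------------------------------------------------
# maximum inscribed circle


def max_inscribed_circle(component: np.ndarray) -> InscribedCircle:
    """Maximum circle fully inside a connected foreground component.

    Center = foreground pixel maximizing the exact Euclidean distance to
    the nearest background pixel (ties: smallest row, then smallest col);
    radius = that maximum distance.  The image border counts as background,
    so the circle never extends past the canvas.
    """
    mask = as_binary_mask(component)
    if mask.sum() == 0:
        raise ValueError("empty component: no inscribed circle")
    padded = np.pad(mask, 1, constant_values=0)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    dist[mask == 0] = 0.0
    idx = int(np.argmax(dist))  # row-major argmax -> smallest row, then col
    row, col = divmod(idx, mask.shape[1])
    return InscribedCircle(center=(float(col), float(row)), radius=float(dist[row, col]))


# ---------------------------------------------------------------------------
# common external tangents


def external_tangent_quad(c1: InscribedCircle, c2: InscribedCircle) -> TangentConstruction:
    """Common external tangents of two circles and the chord-closed quad.

    With u the unit vector from center1 to center2 and d the center
    distance, the two tangent-line unit normals n satisfy
    ``n . u = (r2 - r1) / d`` with opposite perpendicular components; each
    tangent line touches circle i at ``center_i - r_i * n``.  The quad is
    closed by the chords joining the two tangent points on each circle and
    is returned with counter-clockwise vertex order.

    Raises :class:`TangentDegenerateError` when ``d <= |r1 - r2|``.
    """
    p1 = np.asarray(c1.center, dtype=float)
    p2 = np.asarray(c2.center, dtype=float)
    r1, r2 = float(c1.radius), float(c2.radius)
    d = float(np.linalg.norm(p2 - p1))
    if d <= abs(r1 - r2):
        raise TangentDegenerateError(
            f"no external tangents: center distance {d:.6g} <= |r1-r2| = {abs(r1 - r2):.6g}"
        )
    u = (p2 - p1) / d
    perp = np.array([-u[1], u[0]])
    a = (r2 - r1) / d  # component of the normal along u
    b = float(np.sqrt(max(0.0, 1.0 - a * a)))
    n_plus = a * u + b * perp
    n_minus = a * u - b * perp
    quad = np.array(
        [
            p1 - r1 * n_plus,
            p2 - r2 * n_plus,
            p2 - r2 * n_minus,
            p1 - r1 * n_minus,
        ]
    )
    if _signed_area(quad) < 0:
        quad = quad[::-1].copy()
    d1 = (p2 - r2 * n_plus) - (p1 - r1 * n_plus)
    d2 = (p2 - r2 * n_minus) - (p1 - r1 * n_minus)
    t1 = (tuple(p1 - r1 * n_plus), tuple(d1 / np.linalg.norm(d1)))
    t2 = (tuple(p1 - r1 * n_minus), tuple(d2 / np.linalg.norm(d2)))
    return TangentConstruction(l0=(tuple(p1), tuple(p2)), l1=t1, l2=t2, quad=quad)


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
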