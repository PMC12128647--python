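"""Exact polygon geometry shared by the contour modules.

All polygons are (N, 2) float arrays of vertices in Cartesian μm, open
convention (the closing edge last->first is implicit), counterclockwise
unless stated otherwise.
"""
from __future__ import annotations

from math import comb, factorial

import numpy as np
import shapely.geometry as _sg

__all__ = [
    "signed_area",
    "ensure_ccw",
    "polygon_moment",
    "polygon_centroid",
    "central_moments",
    "principal_axis_angle",
    "is_simple",
    "point_in_polygon",
    "ray_radii",
]


def signed_area(vertices: np.ndarray) -> float:
    """Signed area of a polygon (positive for counterclockwise orientation)."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    """Return the polygon with counterclockwise orientation."""
    if signed_area(vertices) < 0:
        return vertices[::-1].copy()
    return vertices


def _simplex_integral(m: int, n: int) -> float:
    # integral of u^m v^n over the unit simplex {u,v>=0, u+v<=1}
    return factorial(m) * factorial(n) / factorial(m + n + 2)


def polygon_moment(vertices: np.ndarray, p: int, q: int) -> float:
    """Exact raw geometric moment ``M_pq = \\iint x^p y^q dA`` over the polygon.

    Computed by signed triangle decomposition against the origin; each edge
    (A, B) contributes the integral over the triangle (0, A, B) weighted by
    the cross product A x B.  Exact for any p, q >= 0.
    """
    A = vertices
    B = np.roll(vertices, -1, axis=0)
    cross = A[:, 0] * B[:, 1] - A[:, 1] * B[:, 0]
    total = np.zeros(len(A))
    for i in range(p + 1):
        for j in range(q + 1):
            coef = comb(p, i) * comb(q, j)
            xa = A[:, 0] ** i * B[:, 0] ** (p - i)
            ya = A[:, 1] ** j * B[:, 1] ** (q - j)
            total += coef * xa * ya * _simplex_integral(i + j, (p - i) + (q - j))
    return float(np.sum(cross * total))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    m00 = polygon_moment(vertices, 0, 0)
    if m00 == 0.0:
        raise ValueError("degenerate polygon with zero area")
    return np.array(
        [polygon_moment(vertices, 1, 0) / m00, polygon_moment(vertices, 0, 1) / m00]
    )


def central_moments(vertices: np.ndarray, max_order: int = 3) -> dict[tuple[int, int], float]:
    """Exact central moments mu_pq up to ``max_order`` (about the area centroid)."""
    c = polygon_centroid(vertices)
    shifted = vertices - c
    out: dict[tuple[int, int], float] = {}
    for p in range(max_order + 1):
        for q in range(max_order + 1 - p):
            out[(p, q)] = polygon_moment(shifted, p, q)
    return out


def principal_axis_angle(mu: dict[tuple[int, int], float]) -> float:
    """Orientation (radians) of the major principal axis from central moments."""
    return 0.5 * np.arctan2(2.0 * mu[(1, 1)], mu[(2, 0)] - mu[(0, 2)])


def is_simple(vertices: np.ndarray) -> bool:
    """True if the closed polygon does not self-intersect."""
    ring = _sg.LinearRing(np.vstack([vertices, vertices[:1]]))
    return bool(ring.is_simple)


def point_in_polygon(point: np.ndarray, vertices: np.ndarray) -> bool:
    return bool(_sg.Polygon(vertices).contains(_sg.Point(point)))


def ray_radii(
    vertices: np.ndarray, origin: np.ndarray, thetas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Radii where rays from ``origin`` at angles ``thetas`` cross the polygon.

    Each edge P_i -> P_{i+1} is intersected with each ray s*(cos t, sin t),
    s > 0, by solving ``s d = P_i + u e`` with u in [0, 1).  When a ray
    crosses the boundary more than once (non-star-shaped contour) the
    farthest crossing is kept and the corresponding flag is set.

    Returns (radii, multi_crossing_flags); radii is NaN where a ray never
    crosses (cannot happen when origin is interior to a closed polygon).
    """
    P = vertices - origin
    E = np.roll(P, -1, axis=0) - P
    d = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)  # (M, 2)

    # cross products, broadcast (M, V)
    dxe = d[:, 0, None] * E[None, :, 1] - d[:, 1, None] * E[None, :, 0]
    pxd = P[None, :, 0] * d[:, 1, None] - P[None, :, 1] * d[:, 0, None]
    pxe = P[:, 0] * E[:, 1] - P[:, 1] * E[:, 0]

    with np.errstate(divide="ignore", invalid="ignore"):
        u = pxd / dxe
        s = pxe[None, :] / dxe
    # half-open window shifted by a tolerance so a ray passing exactly
    # through a vertex is counted once (u=1 on one edge rounds to u=0-eps
    # on the next)
    eps = 1e-9
    hit = (u >= -eps) & (u < 1.0 - eps) & (s > 0.0) & np.isfinite(s)
    n_hits = hit.sum(axis=1)
    radii = np.max(np.where(hit, s, -np.inf), axis=1)
    radii = np.where(np.isfinite(radii), radii, np.nan)
    return radii, n_hits > 1
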