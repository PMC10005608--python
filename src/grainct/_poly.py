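"""Internal 2D polyline helpers shared by the alignment and porosity stages.

Planar points are stored as (y, x) rows, matching array index order of an XY
slice.  Shapely geometries are built with coordinates (x, y), so conversion
always goes through :func:`to_xy` / :func:`from_xy`.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "signed_area",
    "ensure_ccw",
    "polyline_length",
    "resample_closed",
    "resample_open",
    "point_segment_distance",
    "distance_to_polygon_boundary",
    "deepest_hull_defect",
    "to_xy",
]


def to_xy(pts_yx: np.ndarray) -> np.ndarray:
    """(y, x) rows -> (x, y) rows for shapely."""
    return np.asarray(pts_yx)[:, ::-1]


def signed_area(pts_yx: np.ndarray) -> float:
    """Shoelace signed area; positive = counterclockwise in (x, y) axes."""
    p = np.asarray(pts_yx, dtype=float)
    y, x = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(pts_yx: np.ndarray) -> np.ndarray:
    p = np.asarray(pts_yx, dtype=float)
    return p if signed_area(p) >= 0 else p[::-1].copy()


def polyline_length(pts_yx: np.ndarray, closed: bool = False) -> float:
    p = np.asarray(pts_yx, dtype=float)
    if closed:
        p = np.vstack([p, p[:1]])
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def _cumlen(p: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_closed(pts_yx: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a closed polyline to (approximately) uniform arclength.

    The vertex count is round(L / spacing); exact uniform spacing in the
    arclength parameterization of the input polyline.
    """
    p = np.asarray(pts_yx, dtype=float)
    pc = np.vstack([p, p[:1]])
    s = _cumlen(pc)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polyline with zero length")
    n = max(int(round(total / spacing)), 4)
    snew = np.linspace(0.0, total, n, endpoint=False)
    out = np.column_stack([np.interp(snew, s, pc[:, k]) for k in range(2)])
    return out


def resample_open(pts_yx: np.ndarray, n_points: int) -> np.ndarray:
    """Resample an open polyline to n_points uniformly spaced in arclength."""
    p = np.asarray(pts_yx, dtype=float)
    s = _cumlen(p)
    if s[-1] <= 0:
        raise ValueError("degenerate polyline with zero length")
    snew = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(snew, s, p[:, k]) for k in range(2)])


def taubin_smooth(pts_yx: np.ndarray, lam: float = 0.5, mu: float = -0.53,
                  iters: int = 10) -> np.ndarray:
    """Shrinkage-free Taubin smoothing of a closed polyline.

    Alternating positive/negative Laplacian steps remove the half-pixel
    staircase of marching-squares output while preserving enclosed area and
    true corners far better than a plain moving average.
    """
    p = np.asarray(pts_yx, dtype=float).copy()
    for _ in range(iters):
        for f in (lam, mu):
            lap = 0.5 * (np.roll(p, 1, axis=0) + np.roll(p, -1, axis=0)) - p
            p += f * lap
    return p


def point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to segment ab (all 2D)."""
    pts = np.asarray(pts, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def distance_to_polygon_boundary(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to the closed polygon boundary (vertex list)."""
    d = np.full(len(pts), np.inf)
    m = len(poly)
    for k in range(m):
        d = np.minimum(d, point_segment_distance(pts, poly[k], poly[(k + 1) % m]))
    return d


def deepest_hull_defect(pts_yx: np.ndarray):
    """Locate the deepest convexity defect of a closed contour.

    Returns (tip_index, depth, idx_before, idx_after) where tip_index is the
    vertex farthest (perpendicular) from the convex hull boundary, depth that
    distance, and idx_before/idx_after the nearest hull-touching vertices
    reached walking backward/forward along the contour from the tip.
    Ties on depth break toward the smallest x coordinate.

    Returns depth 0 (tip_index -1) for a convex contour.
    """
    p = np.asarray(pts_yx, dtype=float)
    n = len(p)
    if n < 4:
        return -1, 0.0, -1, -1
    hull = ConvexHull(to_xy(p))
    hull_idx = set(int(i) for i in hull.vertices)
    hull_poly = p[list(hull.vertices)]  # ordered along the hull
    d = distance_to_polygon_boundary(p, hull_poly)
    d[list(hull_idx)] = 0.0
    depth = float(d.max())
    if depth <= 1e-9:
        return -1, 0.0, -1, -1
    # tie-break: deepest, then smallest x
    cand = np.flatnonzero(d >= depth - 1e-9)
    tip = int(cand[np.argmin(p[cand, 1])])
    i1 = tip
    while i1 not in hull_idx:
        i1 = (i1 - 1) % n
    i2 = tip
    while i2 not in hull_idx:
        i2 = (i2 + 1) % n
    return tip, depth, i1, i2
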