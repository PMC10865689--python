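"""Bagplots: the 2-D analogue of the boxplot, built on Tukey halfspace depth.

The *bag* is the central convex region holding the deepest 50% of the
observations (the 2-D counterpart of the interquartile range); the
*fence* is the bag inflated by a factor rho (default 3) about the depth
median; points beyond the fence are declared outliers.

Depth is computed exactly (angular sweep over the critical directions
defined by the data), which is comfortably fast for cohort sizes of a
few hundred points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPoint, Point, Polygon

__all__ = ["Bagplot", "halfspace_depth", "compute_bagplot", "classify_regions"]

REGIONS = ("bag", "fence", "outlier")


@dataclass
class Bagplot:
    depth_median: np.ndarray          # 2-vector
    bag_polygon: np.ndarray           # (k, 2) convex polygon vertices
    fence_polygon: np.ndarray         # (k, 2)
    regions: np.ndarray               # per-point label in {bag, fence, outlier}
    depths: np.ndarray                # per-point integer Tukey depth
    fence_factor: float = 3.0
    points: np.ndarray = field(default=None, repr=False)


def halfspace_depth(p: np.ndarray, points: np.ndarray) -> int:
    """Exact Tukey depth: the minimum number of data points in any
    closed halfplane whose boundary passes through ``p``.

    Evaluated by an angular sweep: the count, as a function of the
    halfplane normal's angle, only changes at directions orthogonal to
    some p->data vector, so checking those critical angles and the
    midpoints between consecutive ones is exhaustive.
    """
    p = np.asarray(p, dtype=float)
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        raise ValueError("empty point set")
    diff = points - p
    r = np.linalg.norm(diff, axis=1)
    coincident = int(np.sum(r < 1e-12))
    rest = diff[r >= 1e-12]
    if len(rest) == 0:
        return coincident
    theta = np.arctan2(rest[:, 1], rest[:, 0])
    crit = np.concatenate([theta + np.pi / 2, theta - np.pi / 2]) % (2 * np.pi)
    crit = np.unique(crit)
    mids = (crit + np.diff(np.append(crit, crit[0] + 2 * np.pi)) / 2) % (2 * np.pi)
    angles = np.concatenate([crit, mids])
    normals = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = rest @ normals.T                      # (m, n_angles)
    counts = np.sum(proj >= -1e-12, axis=0)
    return int(counts.min()) + coincident


def _hull_polygon(pts: np.ndarray) -> np.ndarray:
    """Convex hull vertices in order; handles <3 or collinear points."""
    pts = np.asarray(pts, dtype=float)
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        return uniq
    try:
        h = ConvexHull(uniq)
        return uniq[h.vertices]
    except Exception:  # collinear
        return uniq


def _minkowski_interp(outer: np.ndarray, inner: np.ndarray, lam: float) -> np.ndarray:
    """Convex body lam*outer (+) (1-lam)*inner (Minkowski combination).

    Computed as the convex hull of all pairwise combinations of the two
    vertex sets; exact for convex polygons.
    """
    pts = (lam * outer[:, None, :] + (1 - lam) * inner[None, :, :]).reshape(-1, 2)
    return _hull_polygon(pts)


def _poly(vertices: np.ndarray) -> Polygon:
    if len(vertices) >= 3:
        return Polygon(vertices)
    return MultiPoint(vertices).convex_hull.buffer(0)


def _covered(vertices: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Boundary-inclusive point-in-polygon (with small float tolerance)."""
    geom = _poly(vertices)
    out = shapely.covers(geom, [Point(q) for q in points])
    near = shapely.distance(geom, [Point(q) for q in points]) <= 1e-9
    return np.asarray(out) | np.asarray(near)


def compute_bagplot(points: np.ndarray, fence_factor: float = 3.0) -> Bagplot:
    """Construct the bagplot of a 2-D point cloud.

    The bag interpolates (Minkowski combination) between the tightest
    depth contour holding at least floor(n/2) points and the next-deeper
    contour, with the interpolation parameter chosen so that exactly
    floor(n/2) points are inside (boundary-inclusive) for points in
    general position.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(points)
    if n < 5:
        raise ValueError("bagplot needs at least 5 points")
    if np.linalg.matrix_rank(points - points.mean(axis=0)) < 2:
        raise ValueError("points are collinear; jitter the data first")

    depths = np.array([halfspace_depth(q, points) for q in points])
    dmax = depths.max()

    # depth median: centroid of the deepest region
    deepest = points[depths == dmax]
    hull = _hull_polygon(deepest)
    if len(hull) >= 3:
        median = np.asarray(_poly(hull).centroid.coords[0])
    else:
        median = deepest.mean(axis=0)

    target = n // 2
    # tightest contour with >= target points
    kstar = dmax
    for k in range(dmax, 0, -1):
        if np.sum(depths >= k) >= target:
            kstar = k
            break
    outer = _hull_polygon(points[depths >= kstar])
    if kstar < dmax:
        inner = _hull_polygon(points[depths >= kstar + 1])
    else:
        inner = median[None, :]

    n_outer = int(_covered(outer, points).sum())
    if n_outer <= target:
        bag = outer
    else:
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _covered(_minkowski_interp(outer, inner, mid), points).sum() >= target:
                hi = mid
            else:
                lo = mid
        bag = _minkowski_interp(outer, inner, hi)

    fence = median + fence_factor * (bag - median)
    regions = classify_polygons(bag, fence, points)
    return Bagplot(
        depth_median=median,
        bag_polygon=bag,
        fence_polygon=fence,
        regions=regions,
        depths=depths,
        fence_factor=fence_factor,
        points=points,
    )


def classify_polygons(bag: np.ndarray, fence: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Assign each point to bag / fence / outlier (boundary -> inner region)."""
    points = np.asarray(points, dtype=float)
    in_bag = _covered(bag, points)
    in_fence = _covered(fence, points)
    labels = np.where(in_bag, "bag", np.where(in_fence, "fence", "outlier"))
    return labels.astype(object)


def classify_regions(bp: Bagplot, points: np.ndarray) -> np.ndarray:
    """Region labels for arbitrary points under a fitted bagplot."""
    return classify_polygons(bp.bag_polygon, bp.fence_polygon, points)
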