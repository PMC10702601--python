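"""Hidden point removal (HPR) by spherical inversion + convex hull.

A point set seen from viewpoint C is reflected through a sphere of radius
R centered on C: p_hat = p + 2 (R - ||p||) p / ||p|| with coordinates taken
relative to C. Points whose images lie on the convex hull of the inverted
set together with C itself are declared visible. R is tied to the scene as
R = 10**gamma * max ||p - C||; large gamma approximates exact line-of-sight
visibility. The default gamma = 4.5 keeps the hidden-concavity tolerance
below the point spacing of survey-density clouds, so the top surface seen
by a nadir flight grid (the orthoimage winners) survives the filter.

`raycast_visible` is an independent brute-force visibility reference (finite
occluder radius) used for validation; it is O(n^2) and not meant for
production-size clouds.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import DegenerateInputError

__all__ = [
    "spherical_inversion", "hpr_visible", "multiview_visible",
    "raycast_visible", "mean_nn_spacing",
]

DEFAULT_GAMMA = 4.5


def spherical_inversion(points, viewpoint, radius: float) -> np.ndarray:
    """Reflect ``points`` through the sphere of ``radius`` centered at ``viewpoint``.

    Output norms (relative to the viewpoint) satisfy ||p_hat|| = 2R - ||p||,
    with directions preserved.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    c = np.asarray(viewpoint, dtype=np.float64)
    q = pts - c
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError("a point coincides with the viewpoint")
    if radius < norms.max():
        raise DegenerateInputError("inversion radius smaller than the farthest point")
    return c + q + 2.0 * (radius - norms)[:, None] * q / norms[:, None]


def hpr_visible(points, viewpoint, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Indices of points visible from ``viewpoint`` (sorted ascending).

    Degenerate sets (fewer than 4 points, coplanar clouds, hull failure)
    fall back to all-visible with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    c = np.asarray(viewpoint, dtype=np.float64)
    norms = np.linalg.norm(pts - c, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError("a point coincides with the viewpoint")
    if n < 4:
        return np.arange(n, dtype=np.int64)
    radius = 10.0 ** gamma * norms.max()
    inverted = spherical_inversion(pts, c, radius)
    cloud = np.vstack([inverted, c[None, :]])
    try:
        hull = ConvexHull(cloud)
    except QhullError:
        warnings.warn("convex hull failed on degenerate input; returning all points visible")
        return np.arange(n, dtype=np.int64)
    vis = hull.vertices[hull.vertices < n]
    return np.sort(vis).astype(np.int64)


def multiview_visible(points, viewpoints, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Union of per-view visible sets over all ``viewpoints``."""
    viewpoints = np.atleast_2d(np.asarray(viewpoints, dtype=np.float64))
    if len(viewpoints) == 0:
        raise DegenerateInputError("at least one viewpoint is required")
    visible = np.zeros(len(np.atleast_2d(points)), dtype=bool)
    for c in viewpoints:
        visible[hpr_visible(points, c, gamma)] = True
    return np.flatnonzero(visible).astype(np.int64)


def mean_nn_spacing(points) -> float:
    """Mean nearest-neighbor distance — the occluder radius scale."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if len(pts) < 2:
        raise DegenerateInputError("need at least two points")
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(d[:, 1].mean())


def raycast_visible(points, viewpoint, occluder_radius: float) -> np.ndarray:
    """Brute-force visibility: p is hidden if some other point, modeled as a
    sphere of ``occluder_radius``, intersects the open segment C -> p while
    lying nearer to C. Reference implementation for validation only."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    c = np.asarray(viewpoint, dtype=np.float64)
    q = pts - c
    dist = np.linalg.norm(q, axis=1)
    if np.any(dist == 0):
        raise DegenerateInputError("a point coincides with the viewpoint")
    u = q / dist[:, None]
    visible = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        t = q @ u[i]                       # projection of every point on ray i
        perp2 = (dist ** 2) - t ** 2
        blocking = (t > 0) & (t < dist[i] - occluder_radius) & (
            perp2 < occluder_radius ** 2
        )
        blocking[i] = False
        if np.any(blocking):
            visible[i] = False
    return np.flatnonzero(visible).astype(np.int64)
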