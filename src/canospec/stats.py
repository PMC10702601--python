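"""Descriptive analyses of the fused cloud.

* Spearman rank correlation (average ranks; Pearson on ranks, which reduces
  to the classic 1 - 6 sum d_i^2 / (n (n^2 - 1)) formula when untied) and
  per-class attribute correlation matrices with t-approximation p-values.
* Single-tree crown profiles: apex detection and equal-width rings of
  apex distance with per-ring mean elevation and mean NIR, plus the OLS R^2
  of the ring-level NIR trend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConstantInputError, DegenerateInputError
from .types import CLASS_NAMES, PointCloud

__all__ = [
    "spearman_rho", "correlation_matrix", "detect_apex",
    "ring_profile", "linear_r2",
]


def spearman_rho(x, y) -> float:
    """Spearman correlation via average-rank transform + Pearson on ranks."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise DegenerateInputError("inputs differ in length")
    if x.size < 3:
        raise DegenerateInputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Spearman correlation is undefined on constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p via the large-n t approximation with n - 2 df."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def correlation_matrix(cloud: PointCloud,
                       attrs=("x", "y", "z", "r", "g", "b", "nir"),
                       by_class: bool = True, min_points: int = 10):
    """Per-class (or pooled) Spearman matrices over the fused attributes.

    Returns ``{class_name: (rho_df, p_df)}`` of symmetric unit-diagonal
    DataFrames; significance is reported as two-sided p-values from the t
    approximation (the survey convention quotes the P < 0.01 level).
    """
    cols = {a: cloud.attr(a) for a in attrs}
    if by_class:
        ids = cloud.attr("class_id")
        groups = {CLASS_NAMES.get(c, str(c)): ids == c for c in np.unique(ids)}
    else:
        groups = {"all": np.ones(len(cloud), dtype=bool)}
    out = {}
    for name, mask in groups.items():
        n = int(mask.sum())
        if n < min_points:
            raise DegenerateInputError(f"class {name!r} has fewer than {min_points} points")
        k = len(attrs)
        rho = np.eye(k)
        pval = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                r = spearman_rho(cols[attrs[i]][mask], cols[attrs[j]][mask])
                rho[i, j] = rho[j, i] = r
                pval[i, j] = pval[j, i] = _spearman_p(r, n)
        out[name] = (
            pd.DataFrame(rho, index=attrs, columns=attrs),
            pd.DataFrame(pval, index=attrs, columns=attrs),
        )
    return out


def detect_apex(tree_points: PointCloud) -> np.ndarray:
    """Apex = maximum-Z point; ties resolved by distance to the XY centroid."""
    if len(tree_points) == 0:
        raise DegenerateInputError("empty tree")
    zmax = tree_points.z.max()
    cand = np.flatnonzero(tree_points.z == zmax)
    if cand.size > 1:
        cx, cy = tree_points.x.mean(), tree_points.y.mean()
        d2 = (tree_points.x[cand] - cx) ** 2 + (tree_points.y[cand] - cy) ** 2
        cand = cand[[int(d2.argmin())]]
    i = int(cand[0])
    return np.array([tree_points.x[i], tree_points.y[i], tree_points.z[i]])


def ring_profile(tree_points: PointCloud, apex, n_levels: int = 5,
                 distance: str = "3d") -> pd.DataFrame:
    """Equal-width rings of apex distance with per-ring Z_mean and NIR_mean.

    ``distance`` is "3d" (Euclidean from the apex) or "planar" (horizontal
    radius). Ring edges span [0, d_max] exactly; empty rings are flagged
    with NaN means and count 0.
    """
    if n_levels < 2:
        raise DegenerateInputError("need at least 2 levels")
    apex = np.asarray(apex, dtype=np.float64)
    dx = tree_points.x - apex[0]
    dy = tree_points.y - apex[1]
    if distance == "3d":
        d = np.sqrt(dx ** 2 + dy ** 2 + (tree_points.z - apex[2]) ** 2)
    elif distance == "planar":
        d = np.sqrt(dx ** 2 + dy ** 2)
    else:
        raise DegenerateInputError(f"unknown distance mode {distance!r}")
    dmax = d.max()
    if dmax == 0:
        raise DegenerateInputError("all points coincide with the apex")
    edges = np.linspace(0.0, dmax, n_levels + 1)
    level = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_levels - 1)
    nir = tree_points.nir
    rows = []
    for lv in range(n_levels):
        m = level == lv
        rows.append({
            "level": lv + 1,
            "d_lo": edges[lv],
            "d_hi": edges[lv + 1],
            "count": int(m.sum()),
            "z_mean": float(tree_points.z[m].mean()) if m.any() else np.nan,
            "nir_mean": float(nir[m].mean()) if (m.any() and nir is not None) else np.nan,
        })
    return pd.DataFrame(rows)


def linear_r2(level_index, response) -> float:
    """OLS coefficient of determination of ``response`` on ``level_index``."""
    x = np.asarray(level_index, dtype=np.float64).ravel()
    y = np.asarray(response, dtype=np.float64).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DegenerateInputError("need at least 3 levels")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ConstantInputError("R^2 undefined for constant input")
    res = sps.linregress(x, y)
    return float(res.rvalue ** 2)
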