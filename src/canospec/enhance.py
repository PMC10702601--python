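"""Feature enhancement of the fused cloud.

Stages, in pipeline order:

1. *Outlier removal* with an isolation forest. Anomaly degree of a record
   is s(x, psi) = 2 ** (-E[h(x)] / c(psi)), where h(x) is the path length
   to the record's terminating node over randomly built trees and c(psi) is
   the average unsuccessful-search path of a binary search tree:
   c(psi) = 2 H(psi-1) - 2 (psi-1)/psi for psi > 2, 1 for psi = 2, else 0
   (H = exact harmonic number). Scores near 1 mark anomalies.
2. *NIR quantization*: 1-D K-means (Lloyd, best of n_init restarts), the
   number of clusters picked by the elbow (knee) of the SSE curve, and
   pseudo-labels assigned in ascending NIR order 1..K.
3. *Normalization*: per-axis z-score of X, Y, Z (population sd) and RGB
   scaled into [0, 1]; labels untouched.
4. *Split* into train/test/validation (default 8:1:1, seeded shuffle).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin

from .errors import DegenerateInputError
from .types import ClusterCodebook, PointCloud

__all__ = [
    "c_psi", "TreeNode", "build_isolation_tree", "path_length",
    "anomaly_score", "IsolationForestDetector", "remove_outliers",
    "kmeans_fit", "KMeansResult", "sse", "elbow_select_k",
    "NIRQuantizer", "encode_pseudo_labels", "normalize_features",
    "split_dataset", "FEATURE_ATTRS",
]

FEATURE_ATTRS = ("x", "y", "z", "r", "g", "b")
_EULER_GAMMA = 0.5772156649015329


def _harmonic(n: int) -> float:
    """Exact harmonic sum for n <= 1e6; ln(n) + gamma beyond."""
    if n <= 0:
        return 0.0
    if n <= 1_000_000:
        return float(np.sum(1.0 / np.arange(1, n + 1)))
    return math.log(n) + _EULER_GAMMA


def c_psi(psi: int) -> float:
    """Average BST path-length normalizer: piecewise in the subsample size."""
    psi = int(psi)
    if psi > 2:
        return 2.0 * _harmonic(psi - 1) - 2.0 * (psi - 1) / psi
    if psi == 2:
        return 1.0
    return 0.0


# ---------------------------------------------------------------------------
# isolation trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an isolation tree; a leaf has ``feature is None``."""

    n_samples: int
    feature: Optional[int] = None
    threshold: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def build_isolation_tree(X: np.ndarray, rng: np.random.Generator,
                         height_limit: Optional[int] = None) -> TreeNode:
    """Grow one isolation tree on ``X`` (n, d) by random axis/split cuts.

    Growth stops at single records, at the height limit ceil(log2 n), or
    when the subsample is constant in every feature.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if height_limit is None:
        height_limit = max(int(np.ceil(np.log2(max(len(X), 2)))), 1)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        n = idx.size
        if n <= 1 or depth >= height_limit:
            return TreeNode(n_samples=n)
        sub = X[idx]
        lo = sub.min(axis=0)
        hi = sub.max(axis=0)
        usable = np.flatnonzero(hi > lo)
        if usable.size == 0:
            return TreeNode(n_samples=n)
        feat = int(rng.choice(usable))
        thr = float(rng.uniform(lo[feat], hi[feat]))
        mask = sub[:, feat] < thr
        if not mask.any() or mask.all():  # degenerate draw at an extreme
            return TreeNode(n_samples=n)
        return TreeNode(
            n_samples=n, feature=feat, threshold=thr,
            left=grow(idx[mask], depth + 1), right=grow(idx[~mask], depth + 1),
        )

    return grow(np.arange(len(X)), 0)


def path_length(record, tree: TreeNode) -> float:
    """h(x): edges traversed to the terminating node, plus c(size) when the
    node was truncated while still holding more than one record."""
    x = np.asarray(record, dtype=np.float64).ravel()
    node = tree
    edges = 0
    while not node.is_leaf:
        if x.size <= node.feature:
            raise DegenerateInputError("record has fewer features than the tree")
        node = node.left if x[node.feature] < node.threshold else node.right
        edges += 1
    return edges + (c_psi(node.n_samples) if node.n_samples > 1 else 0.0)


def _tree_paths(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Vectorized path lengths of every row of X through one tree."""
    out = np.empty(len(X), dtype=np.float64)

    def descend(node: TreeNode, idx: np.ndarray, depth: int) -> None:
        if node.is_leaf:
            out[idx] = depth + (c_psi(node.n_samples) if node.n_samples > 1 else 0.0)
            return
        mask = X[idx, node.feature] < node.threshold
        descend(node.left, idx[mask], depth + 1)
        descend(node.right, idx[~mask], depth + 1)

    descend(tree, np.arange(len(X)), 0)
    return out


def anomaly_score(record, trees, psi: int) -> float:
    """s(x, psi) = 2 ** (-E[h(x)] / c(psi)); near 1 means anomalous."""
    if not trees:
        raise DegenerateInputError("empty forest")
    mean_h = float(np.mean([path_length(record, t) for t in trees]))
    denom = c_psi(psi)
    if denom <= 0:
        raise DegenerateInputError("c(psi) is zero; subsample too small")
    return float(2.0 ** (-mean_h / denom))


class IsolationForestDetector(OutlierMixin, BaseEstimator):
    """Isolation-forest outlier detector over the fused 7-attribute records.

    Parameters
    ----------
    n_estimators, max_samples : forest size and subsample size psi
        (defaults 100 trees, psi = 256).
    contamination : fraction removed by :meth:`outlier_mask` — the
        ceil(contamination * n) highest-scoring records.
    score_threshold : optional absolute cutoff s0; records with s >= s0 are
        flagged regardless of contamination.
    standardize : z-score features before cutting. The algorithm itself is
        scale-free per tree, but mixed units (meters vs color counts) would
        otherwise skew the random-split budget across features.
    """

    def __init__(self, n_estimators: int = 100, max_samples: int = 256,
                 contamination: float = 0.05, score_threshold: Optional[float] = None,
                 standardize: bool = True, random_state: Optional[int] = None):
        self.n_estimators = n_estimators
        self.max_samples = max_samples
        self.contamination = contamination
        self.score_threshold = score_threshold
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n = len(X)
        if n == 0:
            raise DegenerateInputError("cannot fit on an empty set")
        psi = int(min(self.max_samples, n))
        if psi < self.max_samples:
            warnings.warn(f"subsample size reduced to n = {psi}")
        rng = np.random.default_rng(self.random_state)
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_
        limit = max(int(np.ceil(np.log2(max(psi, 2)))), 1)
        self.trees_ = []
        for _ in range(self.n_estimators):
            idx = rng.choice(n, size=psi, replace=False)
            self.trees_.append(build_isolation_tree(Xs[idx], rng, height_limit=limit))
        self.psi_ = psi
        self.n_features_in_ = X.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        """Anomaly scores in (0, 1); larger is more anomalous."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        Xs = (X - self.mean_) / self.scale_
        h = np.zeros(len(Xs))
        for t in self.trees_:
            h += _tree_paths(t, Xs)
        h /= len(self.trees_)
        return 2.0 ** (-h / c_psi(self.psi_))

    def outlier_mask(self, X) -> np.ndarray:
        """Boolean mask of records to remove (True = outlier)."""
        s = self.score_samples(X)
        n = len(s)
        if self.score_threshold is not None:
            return s >= self.score_threshold
        k = int(np.ceil(self.contamination * n))
        if k <= 0:
            return np.zeros(n, dtype=bool)
        cut = np.argsort(s)[::-1][:k]
        mask = np.zeros(n, dtype=bool)
        mask[cut] = True
        return mask

    def predict(self, X) -> np.ndarray:
        """sklearn convention: +1 inlier, -1 outlier."""
        return np.where(self.outlier_mask(X), -1, 1)


def cloud_features(cloud: PointCloud, attrs=FEATURE_ATTRS + ("nir",)) -> np.ndarray:
    return np.column_stack([cloud.attr(a) for a in attrs])


def remove_outliers(cloud: PointCloud, attrs=FEATURE_ATTRS + ("nir",),
                    contamination: float = 0.05, seed: Optional[int] = 0,
                    **detector_kw):
    """Drop the ceil(contamination * n) most anomalous records.

    Returns ``(kept, removed)`` — a partition of the input cloud.
    """
    if contamination == 0:
        return cloud, cloud.subset(np.zeros(len(cloud), dtype=bool))
    if not 0 < contamination < 0.5:
        raise DegenerateInputError("contamination must be in (0, 0.5)")
    X = cloud_features(cloud, attrs)
    det = IsolationForestDetector(contamination=contamination,
                                  random_state=seed, **detector_kw).fit(X)
    mask = det.outlier_mask(X)
    return cloud.subset(~mask), cloud.subset(mask)


# ---------------------------------------------------------------------------
# K-means on the NIR axis
# ---------------------------------------------------------------------------

@dataclass
class KMeansResult:
    centers: np.ndarray
    sse: float
    history: list = field(default_factory=list)  # SSE after each Lloyd step


def sse(values, centers) -> float:
    """Sum of squared distances of each value to its nearest center."""
    values = np.asarray(values, dtype=np.float64).ravel()
    centers = np.asarray(centers, dtype=np.float64).ravel()
    if centers.size == 0:
        raise DegenerateInputError("centers must be nonempty")
    d2 = (values[:, None] - centers[None, :]) ** 2
    return float(d2.min(axis=1).sum())


def _lloyd(values: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> KMeansResult:
    uniq = np.unique(values)
    centers = rng.choice(uniq, size=k, replace=False).astype(np.float64)
    history = []
    for _ in range(max_iter):
        assign = np.abs(values[:, None] - centers[None, :]).argmin(axis=1)
        new = centers.copy()
        for j in range(k):
            m = assign == j
            if m.any():
                new[j] = values[m].mean()
            else:  # re-seed an empty cluster on the worst-fit value
                worst = np.abs(values - centers[assign]).argmax()
                new[j] = values[worst]
        history.append(sse(values, new))
        if np.array_equal(new, centers):
            break
        centers = new
    return KMeansResult(centers=np.sort(centers), sse=history[-1], history=history)


def kmeans_fit(values, k: int, seed: Optional[int] = 0, n_init: int = 10) -> KMeansResult:
    """1-D Lloyd K-means, best of ``n_init`` seeded restarts by SSE.

    Centers are returned sorted ascending (the pseudo-label order).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    n_distinct = np.unique(values).size
    if k > n_distinct:
        raise DegenerateInputError(f"K = {k} exceeds {n_distinct} distinct values")
    if k < 1:
        raise DegenerateInputError("K must be >= 1")
    root = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_init, 1)):
        res = _lloyd(values, k, root)
        if best is None or res.sse < best.sse - 1e-12:
            best = res
    return best


def elbow_select_k(values, k_range=range(2, 13), seed: Optional[int] = 0,
                   n_init: int = 10, method: str = "curvature"):
    """Pick K at the knee (inflection) of the SSE(k) curve.

    Returns ``(k_star, sse_by_k)``. Two knee definitions are offered:

    * "curvature" (default): the largest second difference of log SSE —
      the k where the relative SSE drop collapses. For K well-separated
      modes the optimal SSE declines convexly all the way to K, so this
      is the rule that recovers the mode count of a clean mixture.
    * "chord": the Kneedle-style maximum normalized distance from the
      curve to the chord joining its endpoints. On multi-scale mixtures
      this lands at the coarse structure below the mode count.

    A flat curve (no knee) falls back to the smallest candidate with a
    warning.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise DegenerateInputError("empty k range")
    if min(ks) < 1 or max(ks) > 20:
        raise DegenerateInputError("k range must lie within [1, 20]")
    n_distinct = np.unique(values).size
    usable = [k for k in ks if k <= n_distinct]
    if not usable:
        warnings.warn("fewer distinct values than any candidate K; using the smallest")
        return ks[0], {}
    sse_by_k = {k: kmeans_fit(values, k, seed=seed, n_init=n_init).sse for k in usable}
    s = np.array([sse_by_k[k] for k in usable], dtype=np.float64)
    karr = np.array(usable, dtype=np.float64)
    if len(usable) < 3 or s[0] - s[-1] <= 1e-12:
        warnings.warn("SSE curve is flat; falling back to the smallest K")
        return usable[0], sse_by_k
    if method == "chord":
        kn = (karr - karr[0]) / (karr[-1] - karr[0])
        sn = (s - s.min()) / (s[0] - s[-1])
        p0 = np.array([kn[0], sn[0]])
        p1 = np.array([kn[-1], sn[-1]])
        chord = p1 - p0
        chord /= np.linalg.norm(chord)
        rel = np.column_stack([kn, sn]) - p0
        dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
        return usable[int(dist.argmax())], sse_by_k
    if method != "curvature":
        raise DegenerateInputError(f"unknown knee method {method!r}")
    logs = np.log(np.maximum(s, 1e-12 * max(s[0], 1.0)))
    drop = logs[:-1] - logs[1:]              # relative drop k -> k+1
    curv = drop[:-1] - drop[1:]              # collapse of the drop at k+1
    return usable[1 + int(curv.argmax())], sse_by_k


class NIRQuantizer(TransformerMixin, BaseEstimator):
    """K-means quantizer of the NIR axis with ascending 1..K pseudo-labels.

    ``n_clusters`` may be an integer or "auto" (elbow selection over
    ``k_range``). After fitting, ``codebook_`` holds the sorted centers,
    ``labels_`` the training labels, ``n_clusters_`` the chosen K.
    """

    def __init__(self, n_clusters="auto", k_range=(2, 12), n_init: int = 10,
                 random_state: Optional[int] = None):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=np.float64).ravel()
        if values.size == 0:
            raise DegenerateInputError("cannot quantize an empty NIR set")
        hist = None
        if self.n_clusters == "auto":
            lo, hi = self.k_range
            k, hist = elbow_select_k(values, range(int(lo), int(hi) + 1),
                                     seed=self.random_state, n_init=self.n_init)
        else:
            k = int(self.n_clusters)
        res = kmeans_fit(values, k, seed=self.random_state, n_init=self.n_init)
        self.codebook_ = ClusterCodebook(res.centers, sse_history=hist)
        self.n_clusters_ = self.codebook_.n_clusters
        self.inertia_ = res.sse
        self.labels_ = self.codebook_.encode(values)
        return self

    def transform(self, X) -> np.ndarray:
        return self.codebook_.encode(np.asarray(X, dtype=np.float64).ravel())

    predict = transform

    def inverse_transform(self, labels) -> np.ndarray:
        return self.codebook_.decode(labels)


def encode_pseudo_labels(cloud: PointCloud, codebook: ClusterCodebook) -> PointCloud:
    """Attach 1..K pseudo-labels (rank of nearest center, 1 = lowest NIR)."""
    return cloud.with_(label=codebook.encode(cloud.attr("nir")))


# ---------------------------------------------------------------------------
# normalization and split
# ---------------------------------------------------------------------------

def normalize_features(cloud: PointCloud, rgb_max: float = 255.0) -> PointCloud:
    """Z-score X/Y/Z per axis (population sd) and scale RGB into [0, 1].

    A zero-variance axis maps to all zeros. Labels, class ids and NIR are
    carried through untouched.
    """
    if len(cloud) < 2:
        raise DegenerateInputError("need at least two points to normalize")

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    kw = {"x": zscore(cloud.x), "y": zscore(cloud.y), "z": zscore(cloud.z)}
    if cloud.has_rgb:
        kw.update(r=cloud.r / rgb_max, g=cloud.g / rgb_max, b=cloud.b / rgb_max)
    return cloud.with_(**kw)


def split_dataset(cloud: PointCloud, ratios=(0.8, 0.1, 0.1), seed: Optional[int] = 0):
    """Seeded disjoint split into (train, test, validation).

    Test and validation take floor(ratio * n) points each; the remainder
    goes to train, so the three parts partition the input exactly.
    """
    n = len(cloud)
    if n < 3:
        raise DegenerateInputError("need at least three points to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise DegenerateInputError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(np.floor(ratios[1] * n))
    n_val = int(np.floor(ratios[2] * n))
    n_train = n - n_test - n_val
    train = cloud.subset(perm[:n_train])
    test = cloud.subset(perm[n_train:n_train + n_test])
    val = cloud.subset(perm[n_train + n_test:])
    return train, test, val
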