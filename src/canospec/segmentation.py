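"""Pseudo-label semantic segmentation of the fused cloud.

NIR reconstruction is cast as a part-segmentation task: each point carries
a 1..K NIR pseudo-label and a network predicts the label from the
normalized (x, y, z, r, g, b) record. The reference backbone is a
pointwise shared MLP with a symmetric max-pooled global feature:

    per-point MLP (d -> h1 -> h2) -> max-pool over the block -> concat
    [point feature, global feature] -> per-point classifier -> K logits

which is order-invariant within a block by construction. Training is plain
SGD on the softmax cross-entropy (survey settings: lr 0.05, batch 4
blocks; epochs 150 at full scale, 30 for desk-scale runs). Alternative
backbones plug in through the same forward/backward contract
(`Backbone`). Evaluation uses the confusion-matrix metrics oAcc
(trace over total) and mIoU (mean per-class intersection over union).

Fixed-size blocks are spatially contiguous grid tiles, subsampled or
padded to ``n_points``, with the block -> point index map retained so
per-point predictions can be un-batched (overlap resolved by majority
vote).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import DegenerateInputError

__all__ = [
    "make_blocks", "PointNetBackbone", "PointNetSegmenter",
    "confusion", "oacc", "miou",
]


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------

def make_blocks(xy: np.ndarray, n_points: int = 4096, seed=0) -> list:
    """Partition points into fixed-size spatial blocks (index arrays).

    The XY extent is tiled so a tile holds on the order of ``n_points``
    points; each tile's points are shuffled and chunked into blocks of
    exactly ``n_points``, the last chunk padded by resampling within the
    tile. Every point appears in at least one block.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
    n = len(xy)
    if n == 0:
        raise DegenerateInputError("empty cloud")
    rng = np.random.default_rng(seed)
    if n <= n_points:
        idx = rng.permutation(n)
        pad = rng.choice(n, size=n_points - n, replace=True) if n < n_points else \
            np.empty(0, dtype=np.int64)
        return [np.concatenate([idx, pad])]
    span_x = max(np.ptp(xy[:, 0]), 1e-9)
    span_y = max(np.ptp(xy[:, 1]), 1e-9)
    n_tiles = max(int(round(n / n_points)), 1)
    tile = float(np.sqrt(span_x * span_y / n_tiles)) if n_tiles > 1 else max(span_x, span_y)
    cx = np.floor((xy[:, 0] - xy[:, 0].min()) / tile).astype(np.int64)
    cy = np.floor((xy[:, 1] - xy[:, 1].min()) / tile).astype(np.int64)
    cell = cx * (cy.max() + 1) + cy
    blocks = []
    for c in np.unique(cell):
        members = np.flatnonzero(cell == c)
        members = members[rng.permutation(len(members))]
        for s in range(0, len(members), n_points):
            chunk = members[s:s + n_points]
            if len(chunk) < n_points:
                pad = rng.choice(members, size=n_points - len(chunk), replace=True)
                chunk = np.concatenate([chunk, pad])
            blocks.append(chunk)
    return blocks


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


class PointNetBackbone:
    """Pointwise shared-MLP backbone with manual gradients.

    Weights are stored in ``params`` (dict of arrays). ``forward`` maps a
    (B, N, d) batch to (B, N, K) logits; ``backward`` consumes d(logits)
    and returns parameter gradients.
    """

    def __init__(self, n_features: int, n_classes: int,
                 hidden=(32, 64), classifier=(64,), rng=None):
        rng = rng or np.random.default_rng(0)
        h1, h2 = hidden
        (c1,) = classifier
        self.sizes = (n_features, h1, h2, c1, n_classes)

        def init(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

        self.params = {
            "W1": init(n_features, h1), "b1": np.zeros(h1),
            "W2": init(h1, h2), "b2": np.zeros(h2),
            "W3": init(2 * h2, c1), "b3": np.zeros(c1),
            "W4": init(c1, n_classes), "b4": np.zeros(n_classes),
        }

    def forward(self, X: np.ndarray):
        p = self.params
        Z1 = X @ p["W1"] + p["b1"]
        A1 = _relu(Z1)
        Z2 = A1 @ p["W2"] + p["b2"]
        A2 = _relu(Z2)
        pool_idx = A2.argmax(axis=1)                      # (B, h2)
        G = np.take_along_axis(A2, pool_idx[:, None, :], axis=1)  # (B, 1, h2)
        C = np.concatenate([A2, np.broadcast_to(G, A2.shape)], axis=-1)
        Z3 = C @ p["W3"] + p["b3"]
        A3 = _relu(Z3)
        logits = A3 @ p["W4"] + p["b4"]
        cache = (X, Z1, A1, Z2, A2, pool_idx, C, Z3, A3)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache):
        p = self.params
        X, Z1, A1, Z2, A2, pool_idx, C, Z3, A3 = cache
        h2 = A2.shape[-1]
        grads = {}
        grads["W4"] = np.einsum("bnc,bnk->ck", A3, dlogits)
        grads["b4"] = dlogits.sum(axis=(0, 1))
        dZ3 = (dlogits @ p["W4"].T) * (Z3 > 0)
        grads["W3"] = np.einsum("bnc,bnh->ch", C, dZ3)
        grads["b3"] = dZ3.sum(axis=(0, 1))
        dC = dZ3 @ p["W3"].T
        dA2 = dC[..., :h2].copy()
        dG = dC[..., h2:].sum(axis=1)                     # (B, h2)
        route = np.zeros_like(A2)
        np.put_along_axis(route, pool_idx[:, None, :], dG[:, None, :], axis=1)
        dA2 += route
        dZ2 = dA2 * (Z2 > 0)
        grads["W2"] = np.einsum("bnd,bnh->dh", A1, dZ2)
        grads["b2"] = dZ2.sum(axis=(0, 1))
        dZ1 = (dZ2 @ p["W2"].T) * (Z1 > 0)
        grads["W1"] = np.einsum("bnd,bnh->dh", X, dZ1)
        grads["b1"] = dZ1.sum(axis=(0, 1))
        return grads

    def sgd_step(self, grads, lr: float) -> None:
        for k, g in grads.items():
            self.params[k] -= lr * g


def _softmax(logits):
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class PointNetSegmenter(ClassifierMixin, BaseEstimator):
    """Per-point pseudo-label classifier over fixed-size spatial blocks.

    Parameters mirror the survey training settings: ``lr`` 0.05, ``batch_size``
    4 blocks; ``epochs`` defaults to the desk-scale 30 (150 at full survey
    scale); ``n_points`` 4096 points per block. ``backbone_factory`` allows
    plugging an alternative architecture with the same forward/backward
    contract.

    ``fit(X, y, xy=..., validation=(Xv, yv, xyv))`` expects features
    already normalized (z-scored coordinates, [0,1] colors) and labels in
    1..K; ``history_`` records per-epoch train loss and, when a validation
    set is supplied, validation overall accuracy.
    """

    def __init__(self, lr: float = 0.05, batch_size: int = 4, epochs: int = 30,
                 n_points: int = 4096, hidden=(32, 64), classifier=(64,),
                 backbone_factory=None, random_state=None):
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.n_points = n_points
        self.hidden = hidden
        self.classifier = classifier
        self.backbone_factory = backbone_factory
        self.random_state = random_state

    def _blockify(self, X, xy, seed):
        if xy is None:
            xy = X[:, :2]
        blocks = make_blocks(xy, n_points=self.n_points, seed=seed)
        return np.stack([X[b] for b in blocks]), blocks

    def fit(self, X, y, xy=None, validation=None):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.int64).ravel()
        if len(X) != y.size:
            raise DegenerateInputError("X and y length mismatch")
        if self.lr <= 0 or self.epochs < 1:
            raise DegenerateInputError("lr must be > 0 and epochs >= 1")
        self.classes_ = np.unique(y)
        if self.classes_.size == 1:
            warnings.warn("single-class training set; the classifier is degenerate")
        k = self.classes_.size
        rng = np.random.default_rng(self.random_state)

        factory = self.backbone_factory or (
            lambda d, k_, r: PointNetBackbone(d, k_, self.hidden, self.classifier, rng=r)
        )
        self.backbone_ = factory(X.shape[1], k, rng)
        self.n_features_in_ = X.shape[1]
        # internal standardization layer: puts meter-scale coordinates and
        # [0,1] colors on equal footing at the first shared-MLP layer
        self.feat_mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.feat_scale_ = np.where(sd > 0, sd, 1.0)
        X = (X - self.feat_mean_) / self.feat_scale_

        y_idx = np.searchsorted(self.classes_, y)
        eye = np.eye(k)

        self.history_ = {"train_loss": [], "val_oacc": []}
        for _ in range(self.epochs):
            # blocks are re-drawn every epoch: varying the block composition
            # keeps the pooled global feature from memorizing one partition
            bX, blocks = self._blockify(X, xy, seed=int(rng.integers(2 ** 31)))
            onehot = eye[np.stack([y_idx[b] for b in blocks])]
            n_blocks = len(bX)
            order = rng.permutation(n_blocks)
            losses = []
            for s in range(0, n_blocks, self.batch_size):
                sel = order[s:s + self.batch_size]
                logits, cache = self.backbone_.forward(bX[sel])
                prob = _softmax(logits)
                m = prob.shape[0] * prob.shape[1]
                eps = 1e-12
                loss = -np.sum(onehot[sel] * np.log(prob + eps)) / m
                dlogits = (prob - onehot[sel]) / m
                grads = self.backbone_.backward(dlogits, cache)
                self.backbone_.sgd_step(grads, self.lr)
                losses.append(loss)
            self.history_["train_loss"].append(float(np.mean(losses)))
            if validation is not None:
                Xv, yv = validation[0], np.asarray(validation[1]).ravel()
                xyv = validation[2] if len(validation) > 2 else None
                pred = self.predict(Xv, xy=xyv)
                self.history_["val_oacc"].append(float(np.mean(pred == yv)))
        return self

    def predict_block_logits(self, block_features: np.ndarray) -> np.ndarray:
        """(B, N, d) -> (B, N, K) logits for pre-assembled blocks."""
        logits, _ = self.backbone_.forward(block_features)
        return logits

    def predict(self, X, xy=None) -> np.ndarray:
        """Per-point labels, un-batched by majority vote over block overlap."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise DegenerateInputError("feature schema mismatch with the fitted model")
        Xs = (X - self.feat_mean_) / self.feat_scale_
        bX, blocks = self._blockify(Xs, xy, seed=0)
        logits = self.predict_block_logits(bX)
        hard = logits.argmax(axis=-1)
        votes = np.zeros((len(X), self.classes_.size), dtype=np.int64)
        for bi, b in enumerate(blocks):
            np.add.at(votes, (b, hard[bi]), 1)
        return self.classes_[votes.argmax(axis=1)]

    def save(self, path) -> None:
        np.savez(
            path, classes=self.classes_, sizes=np.array(self.backbone_.sizes),
            n_points=np.array(self.n_points),
            feat_mean=self.feat_mean_, feat_scale=self.feat_scale_,
            **{f"param_{k}": v for k, v in self.backbone_.params.items()},
        )

    @classmethod
    def load(cls, path, **kw) -> "PointNetSegmenter":
        data = np.load(path)
        sizes = data["sizes"]
        kw.setdefault("n_points", int(data["n_points"]))
        model = cls(hidden=(int(sizes[1]), int(sizes[2])),
                    classifier=(int(sizes[3]),), **kw)
        model.classes_ = data["classes"]
        model.backbone_ = PointNetBackbone(int(sizes[0]), int(sizes[4]),
                                           model.hidden, model.classifier)
        for k in model.backbone_.params:
            model.backbone_.params[k] = data[f"param_{k}"]
        model.n_features_in_ = int(sizes[0])
        model.feat_mean_ = data["feat_mean"]
        model.feat_scale_ = data["feat_scale"]
        return model


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion(y_true, y_pred, labels) -> np.ndarray:
    """Exact count matrix p_ij (row i = true, column j = predicted)."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.size != y_pred.size:
        raise DegenerateInputError("label vectors differ in length")
    labels = np.asarray(labels)
    index = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    cm = np.zeros((k, k), dtype=np.int64)
    try:
        ti = np.array([index[v] for v in y_true])
        pi = np.array([index[v] for v in y_pred])
    except KeyError as e:
        raise DegenerateInputError(f"label {e} outside the declared label set")
    np.add.at(cm, (ti, pi), 1)
    return cm


def oacc(cm: np.ndarray) -> float:
    """Overall accuracy: trace over total count."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise DegenerateInputError("empty confusion matrix")
    return float(np.trace(cm) / total)


def miou(cm: np.ndarray) -> float:
    """Mean over non-empty classes of p_ii / (row_i + col_i - p_ii)."""
    cm = np.asarray(cm, dtype=np.float64)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    denom = row + col - np.diag(cm)
    present = denom > 0
    if not present.any():
        raise DegenerateInputError("no class has any true or predicted instance")
    if not present.all():
        warnings.warn("classes with no instances are skipped in mIoU")
    return float(np.mean(np.diag(cm)[present] / denom[present]))
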