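"""K-nearest-neighbor classification under eight distance metrics.

The metrics are Euclidean, standardized Euclidean (per-dimension scaling by
the training standard deviations), Minkowski (order p), Chebyshev, city
block, cosine, correlation and Mahalanobis (training covariance, ridge-
regularized when near-singular). Prediction is a majority vote over the K
nearest training samples; vote ties break toward the class with the smaller
summed distance, then toward the earlier class in D < A < S order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

METRICS = ("euclidean", "std_euclidean", "minkowski", "chebyshev",
           "cityblock", "cosine", "correlation", "mahalanobis")

CLASS_ORDER = ("D", "A", "S")

#: scale floor for standardized Euclidean when a feature is constant
_S_FLOOR = 1e-8


@dataclass
class DistanceSpec:
    """A named metric with its parameters.

    ``p`` applies to Minkowski; ``S`` is the per-dimension scale vector of
    standardized Euclidean (V = diag(S^2)); ``C`` is the Mahalanobis
    covariance matrix.
    """

    name: str
    p: float = 2.0
    S: np.ndarray | None = None
    C: np.ndarray | None = None

    def __post_init__(self):
        if self.name not in METRICS:
            raise ValueError(f"unknown metric {self.name!r}")
        if self.name == "minkowski" and self.p < 1:
            raise ValueError("Minkowski exponent p must be >= 1")
        if self.S is not None:
            self.S = np.asarray(self.S, dtype=float)
            if np.any(self.S <= 0):
                raise ValueError("scale vector S must be strictly positive")
        if self.C is not None:
            self.C = np.asarray(self.C, dtype=float)


def _check_defined(X, name):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if name == "cosine" and np.any(np.linalg.norm(X, axis=1) == 0):
        raise ValueError("cosine distance undefined for a zero-norm vector")
    if name == "correlation":
        centered = X - X.mean(axis=1, keepdims=True)
        if np.any(np.linalg.norm(centered, axis=1) == 0):
            raise ValueError("correlation distance undefined for a constant vector")
    return X


def pairwise_distance(V, W, spec: DistanceSpec) -> np.ndarray:
    """All pairwise distances between rows of V and rows of W."""
    V = _check_defined(V, spec.name)
    W = _check_defined(W, spec.name)
    if V.shape[1] != W.shape[1]:
        raise ValueError("dimension mismatch")
    name = spec.name
    if name == "euclidean":
        return cdist(V, W, "euclidean")
    if name == "std_euclidean":
        if spec.S is None:
            raise ValueError("std_euclidean requires the scale vector S")
        return cdist(V, W, "seuclidean", V=spec.S ** 2)
    if name == "minkowski":
        return cdist(V, W, "minkowski", p=spec.p)
    if name == "chebyshev":
        return cdist(V, W, "chebyshev")
    if name == "cityblock":
        return cdist(V, W, "cityblock")
    if name == "cosine":
        return cdist(V, W, "cosine")
    if name == "correlation":
        return cdist(V, W, "correlation")
    if name == "mahalanobis":
        if spec.C is None:
            raise ValueError("mahalanobis requires the covariance matrix C")
        return cdist(V, W, "mahalanobis", VI=np.linalg.inv(spec.C))
    raise ValueError(name)


def distance(v, w, spec: DistanceSpec) -> float:
    """Distance between two vectors under the spec'd metric."""
    return float(pairwise_distance(np.atleast_2d(v), np.atleast_2d(w), spec)[0, 0])


@dataclass
class TrainedKNN:
    train_X: np.ndarray
    train_y: np.ndarray
    K: int
    spec: DistanceSpec
    classes: tuple = CLASS_ORDER
    is_augmented: np.ndarray | None = None  # provenance, carried for audits
    ridge: float = field(default=0.0)


def _regularized_cov(X: np.ndarray) -> tuple:
    """Training covariance with a ridge when ill-conditioned (few samples in
    many dimensions makes the plain estimate singular)."""
    C = np.cov(X, rowvar=False)
    C = np.atleast_2d(C)
    ridge = 0.0
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > 1e10:
        ridge = 1e-6 * np.trace(C) / C.shape[0]
        if ridge <= 0:
            ridge = 1e-6
        C = C + ridge * np.eye(C.shape[0])
    return C, ridge


def knn_fit(X, y, K: int = 5, metric: str = "mahalanobis", p: float = 2.0,
            classes: tuple = CLASS_ORDER,
            is_augmented=None) -> TrainedKNN:
    """Store the training set and derive metric parameters from it only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n, d) with matching labels")
    if not 1 <= K <= X.shape[0]:
        raise ValueError(f"K={K} must be in [1, n_train={X.shape[0]}]")
    spec = DistanceSpec(name=metric, p=p)
    ridge = 0.0
    if metric == "std_euclidean":
        S = X.std(axis=0, ddof=1)
        if np.any(S < _S_FLOOR):
            warnings.warn("constant feature: scale floored for std_euclidean")
            S = np.maximum(S, _S_FLOOR)
        spec.S = S
    elif metric == "mahalanobis":
        spec.C, ridge = _regularized_cov(X)
    aug = (np.zeros(len(y), dtype=bool) if is_augmented is None
           else np.asarray(is_augmented, dtype=bool))
    return TrainedKNN(X.copy(), y.copy(), K, spec, tuple(classes), aug, ridge)


def knn_predict(model: TrainedKNN, Xq) -> np.ndarray:
    """Majority vote among the K nearest training samples.

    Vote ties break toward the smaller summed neighbor distance, then
    toward the earlier class in the model's class order.
    """
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    if Xq.shape[1] != model.train_X.shape[1]:
        raise ValueError("query dimension mismatch")
    D = pairwise_distance(Xq, model.train_X, model.spec)
    K = model.K
    nn = np.argpartition(D, K - 1, axis=1)[:, :K] if K < D.shape[1] \
        else np.tile(np.arange(D.shape[1]), (D.shape[0], 1))
    classes = list(model.classes)
    extra = [c for c in np.unique(model.train_y) if c not in classes]
    classes = classes + sorted(extra)
    out = np.empty(Xq.shape[0], dtype=object)
    for i in range(Xq.shape[0]):
        idx = nn[i]
        labs = model.train_y[idx]
        dists = D[i, idx]
        best, key = None, None
        for rank, c in enumerate(classes):
            m = labs == c
            votes = int(m.sum())
            if votes == 0:
                continue
            cand = (-votes, float(dists[m].sum()), rank)
            if key is None or cand < key:
                key, best = cand, c
        out[i] = best
    return out
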