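"""Minimum-redundancy maximum-relevance (MRMR) feature ranking, MIQ variant.

Relevance of a feature f is its mutual information with the class labels,
r_f = I(f, y); redundancy is the mean mutual information with the already
selected set h, e_f = (1/|h|) sum_{z in h} I(f, z). Candidates are ranked by
the mutual-information quotient q_f = r_f / e_f under a forward-selection
scheme:

    1. start with h empty;
    2. seed with the most relevant feature;
    3. while some unselected feature has nonzero relevance and zero
       redundancy, add the most relevant such feature;
    5. then repeatedly add the unselected feature with the largest MIQ
       among those with nonzero relevance;
    7. finally append zero-relevance features in seeded-random order.

Mutual information is the plug-in estimate on discretized features
(equal-width bins by default). "Zero" means below a small tolerance eps:
the plug-in estimate of an independent pair is positive with probability
one, so a literal zero would make steps 3 and 7 dead code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOG_BASE = {"bits": 2.0, "nats": np.e}


@dataclass
class RankedFeatures:
    """Output of the forward selection.

    ``order`` is a permutation of feature indices; ``scores[i]`` is the score
    under which ``order[i]`` was picked (relevance in the seeding/zero-
    redundancy phases, MIQ in the quotient phase, NaN for zero-relevance
    leftovers); ``phase[i]`` is the algorithm step (2, 3, 5 or 7).
    """

    order: np.ndarray
    scores: np.ndarray
    phase: np.ndarray


@dataclass
class MrmrConfig:
    n_bins: int = 10
    eps: float = 1e-12
    unit: str = "bits"
    binning: str = "width"  # "width" (equal-width) or "frequency" (quantile)
    seed: int = 0


def _mi_codes(ai: np.ndarray, ka: int, bi: np.ndarray, kb: int) -> float:
    """Plug-in MI in nats from 0-based integer codes (no re-encoding)."""
    joint = np.bincount(ai * kb + bi, minlength=ka * kb).astype(float)
    joint = joint.reshape(ka, kb) / len(ai)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())
    return max(mi, 0.0)


def mutual_information(a, b, unit: str = "bits") -> float:
    """Plug-in mutual information of two discrete vectors.

    Cells with zero joint probability contribute nothing (0 log 0 = 0).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = int(ai.max()) + 1, int(bi.max()) + 1
    return _mi_codes(ai, ka, bi, kb) / np.log(LOG_BASE[unit])


def discretize_column(x, n_bins: int, binning: str = "width") -> np.ndarray:
    """Bin one feature column into 1..n_bins (top edge closed); constant
    columns map to bin 1."""
    x = np.asarray(x, dtype=float)
    if binning == "width":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.ones(len(x), dtype=np.int64)
        # bins closed at their top edge: (lo + (b-1)w, lo + bw]
        b = np.ceil((x - lo) / (hi - lo) * n_bins).astype(np.int64)
        return np.clip(b, 1, n_bins)
    if binning == "frequency":
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, x, side="left").astype(np.int64) + 1
    raise ValueError(f"unknown binning {binning!r}")


def discretize_features(X, n_bins: int = 10, binning: str = "width") -> np.ndarray:
    """Per-column discretization of a feature matrix."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(X, dtype=float)
    return np.column_stack([discretize_column(X[:, j], n_bins, binning)
                            for j in range(X.shape[1])])


def relevance(fi, y, unit: str = "bits") -> float:
    """I(feature, labels) on an already-discretized feature column."""
    return mutual_information(fi, y, unit)


def redundancy(fi, selected_columns, unit: str = "bits") -> float:
    """Mean I(feature, z) over the selected set (discretized columns)."""
    if len(selected_columns) == 0:
        raise ValueError("selected set must be nonempty")
    return float(np.mean([mutual_information(fi, z, unit)
                          for z in selected_columns]))


def mrmr_rank(X, y, cfg: MrmrConfig | None = None) -> RankedFeatures:
    """Rank all features by the forward-selection scheme described above.

    X is (n_samples, n_features) real-valued (discretized internally);
    y is the label vector. Argmax ties break toward the lowest feature
    index; the step-7 shuffle uses ``cfg.seed``.
    """
    cfg = cfg or MrmrConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    D = discretize_features(X, cfg.n_bins, cfg.binning)
    _, yi = np.unique(np.asarray(y), return_inverse=True)
    ky = int(yi.max()) + 1
    nfeat = D.shape[1]
    log_b = np.log(LOG_BASE[cfg.unit])
    codes = np.ascontiguousarray(D - 1)  # 0-based bin codes per column
    kb = cfg.n_bins
    rel = np.array([_mi_codes(codes[:, j], kb, yi, ky) / log_b
                    for j in range(nfeat)])

    order, scores, phase = [], [], []
    selected = np.zeros(nfeat, dtype=bool)
    red_sum = np.zeros(nfeat)  # sum of I(f, z) over selected z

    def add(j, score, step):
        order.append(j)
        scores.append(score)
        phase.append(step)
        selected[j] = True
        cj = codes[:, j]
        for k in range(nfeat):
            if not selected[k]:
                red_sum[k] += _mi_codes(codes[:, k], kb, cj, kb) / log_b

    # step 2: seed with the largest relevance
    seed_j = int(np.argmax(rel))
    add(seed_j, rel[seed_j], 2)

    nonzero = rel > cfg.eps

    # steps 3-4: nonzero relevance, zero redundancy, by relevance
    while True:
        cand = ~selected & nonzero & (red_sum / selected.sum() <= cfg.eps)
        if not cand.any():
            break
        j = int(np.argmax(np.where(cand, rel, -np.inf)))
        add(j, rel[j], 3)

    # steps 5-6: nonzero relevance, by MIQ = relevance / redundancy
    while True:
        cand = ~selected & nonzero
        if not cand.any():
            break
        e = red_sum / selected.sum()
        with np.errstate(divide="ignore"):
            q = np.where(cand, rel / np.maximum(e, cfg.eps), -np.inf)
        j = int(np.argmax(q))
        add(j, q[j], 5)

    # step 7: zero-relevance leftovers in seeded-random order
    rest = np.flatnonzero(~selected)
    if len(rest):
        rng = np.random.default_rng(cfg.seed)
        for j in rng.permutation(rest):
            order.append(int(j))
            scores.append(np.nan)
            phase.append(7)
            selected[j] = True

    return RankedFeatures(np.array(order), np.array(scores), np.array(phase))


def select_top(ranked: RankedFeatures, k: int) -> np.ndarray:
    """First k indices of the ranking, order preserved."""
    n = len(ranked.order)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    return ranked.order[:k].copy()
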