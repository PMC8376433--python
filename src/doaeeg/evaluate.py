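"""Cross-validated evaluation of the classification pipeline.

Samples (epoch feature vectors) are randomly partitioned into k
near-equal folds. Per fold the training rows are z-scored (training
statistics), augmented with Gaussian-noise copies, MRMR-ranked and reduced
to the top-k features, and a KNN model is fitted; the held-out rows —
always original, never augmented — are standardized with the training
scaler and predicted. Predictions from all folds aggregate into a single
3x3 confusion matrix (rows = actual D, A, S; columns = predicted), from
which overall accuracy and per-class sensitivity are reported in percent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .augment import AugmentConfig, augment_training_set
from .knn import CLASS_ORDER, knn_fit, knn_predict
from .mrmr import MrmrConfig, mrmr_rank, select_top


@dataclass
class FoldAssignment:
    """Fold index (1..k) per sample."""

    folds: np.ndarray
    k: int
    seed: int


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes) ints, rows = actual
    classes: tuple = CLASS_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts shape must match the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class CVConfig:
    """One evaluation configuration (the defaults are the method's
    operating point: SPWVD map, 16 gray levels, MRMR top-30, KNN with K=5
    and Mahalanobis distance, augmentation m=35 at variance 0.1)."""

    n_folds: int = 10
    stratified: bool = False
    metric: str = "mahalanobis"
    knn_k: int = 5
    minkowski_p: float = 2.0
    select_k: int = 30
    mi_bins: int = 10
    aug_multiple: int = 35
    aug_variance: float = 0.1
    standardize: bool = True
    seed: int = 0


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    accuracy: float  # percent
    sensitivity: dict  # class -> percent
    config: dict = field(default_factory=dict)
    selected: list = field(default_factory=list)  # per-fold selected indices


def kfold_split(n: int, k: int, seed: int = 0, stratified: bool = False,
                y=None) -> FoldAssignment:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    idx = np.arange(n)
    folds = np.zeros(n, dtype=int)
    if stratified:
        if y is None:
            raise ValueError("stratified split needs labels")
        splitter = StratifiedKFold(k, shuffle=True, random_state=seed)
        it = splitter.split(idx, np.asarray(y))
    else:
        splitter = KFold(k, shuffle=True, random_state=seed)
        it = splitter.split(idx)
    for f, (_, test) in enumerate(it, start=1):
        folds[test] = f
    return FoldAssignment(folds, k, seed)


def confusion_matrix(actual, predicted, classes: tuple = CLASS_ORDER
                     ) -> ConfusionMatrix:
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if len(actual) != len(predicted):
        raise ValueError("length mismatch")
    pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        counts[pos[a], pos[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def sensitivity(cm: ConfusionMatrix, cls: str) -> float:
    """Per-class sensitivity in percent: 100 * diagonal / row sum."""
    i = cm.classes.index(cls)
    row = cm.counts[i].sum()
    if row == 0:
        return float("nan")
    return 100.0 * float(cm.counts[i, i]) / row


def per_class_sensitivity(cm: ConfusionMatrix) -> dict:
    return {c: sensitivity(cm, c) for c in cm.classes}


def run_cv(X, y, cfg: CVConfig | None = None) -> EvaluationReport:
    """Cross-validate the selection + classification pipeline on a feature
    table. X is (n_samples, n_features); y holds the D/A/S labels."""
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples of every class")
    fa = kfold_split(len(y), cfg.n_folds, cfg.seed, cfg.stratified, y)
    # a fold whose training part misses a class cannot vote for it
    for f in range(1, cfg.n_folds + 1):
        if len(np.unique(y[fa.folds != f])) < len(classes) and not cfg.stratified:
            warnings.warn("a class is absent from a training fold; "
                          "refitting with stratified folds")
            fa = kfold_split(len(y), cfg.n_folds, cfg.seed, True, y)
            break
    actual = np.empty(len(y), dtype=object)
    predicted = np.empty(len(y), dtype=object)
    selected_per_fold = []
    for f in range(1, cfg.n_folds + 1):
        test = fa.folds == f
        train = ~test
        Xtr, ytr = X[train], y[train]
        Xte = X[test]
        if cfg.standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        aug_cfg = AugmentConfig(cfg.aug_multiple, cfg.aug_variance,
                                seed=cfg.seed * 1009 + f)
        Xa, ya, flags = augment_training_set(Xtr, ytr, aug_cfg)
        ranked = mrmr_rank(Xa, ya, MrmrConfig(n_bins=cfg.mi_bins,
                                              seed=cfg.seed * 31 + f))
        k_sel = min(cfg.select_k, X.shape[1])
        sel = select_top(ranked, k_sel)
        selected_per_fold.append(sel.tolist())
        model = knn_fit(Xa[:, sel], ya, K=cfg.knn_k, metric=cfg.metric,
                        p=cfg.minkowski_p, is_augmented=flags)
        pred = knn_predict(model, Xte[:, sel])
        actual[test] = y[test]
        predicted[test] = pred
        # provenance audit: held-out rows are original by construction,
        # and every augmented row stayed inside the training model
        assert model.is_augmented.sum() == len(ytr) * cfg.aug_multiple
    cm = confusion_matrix(actual, predicted)
    return EvaluationReport(
        confusion=cm,
        accuracy=accuracy(cm),
        sensitivity=per_class_sensitivity(cm),
        config=asdict(cfg),
        selected=selected_per_fold,
    )


def run_cv_per_subject(X, y, subjects, cfg: CVConfig | None = None) -> dict:
    """Independent cross-validation per subject (the default grouping for
    clinical recordings); returns {subject_id: EvaluationReport}."""
    subjects = np.asarray(subjects)
    out = {}
    for s in np.unique(subjects):
        m = subjects == s
        out[str(s)] = run_cv(np.asarray(X)[m], np.asarray(y)[m], cfg)
    return out


def run_cv_per_channel(X, y, feature_names, cfg: CVConfig | None = None
                       ) -> dict:
    """One report per channel (using only that channel's four texture
    features) plus an "All" report on the full feature set. Channel
    membership is taken from the ``<channel>_<feature>`` column names; the
    fold seed is shared across reports."""
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    channels = []
    for name in feature_names:
        ch = name.rsplit("_", 1)[0]
        if ch not in channels:
            channels.append(ch)
    out = {}
    for ch in channels:
        cols = [j for j, name in enumerate(feature_names)
                if name.rsplit("_", 1)[0] == ch]
        sub = replace(cfg, select_k=min(cfg.select_k, len(cols)))
        out[ch] = run_cv(X[:, cols], y, sub)
    out["All"] = run_cv(X, y, cfg)
    return out


def sweep(X, y, base: CVConfig, grid: dict) -> list:
    """Cartesian sweep over CVConfig fields; fold seeds are shared across
    grid cells. Returns a list of (params dict, EvaluationReport)."""
    keys = list(grid)
    results = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        results.append((params, run_cv(X, y, replace(base, **params))))
    return results
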