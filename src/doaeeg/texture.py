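"""GLCM texture features of time-frequency maps.

Each channel's time-frequency map is treated as a grayscale image
(rows = frequency, columns = time), quantized to L gray levels, and
summarized by a normalized gray-level co-occurrence matrix (GLCM) G. Four
Haralick statistics are taken per channel,

    contrast     c = sum_ij (i-j)^2 G(i,j)
    correlation  r = sum_ij (i-mu_i)(j-mu_j) G(i,j) / (sigma_i sigma_j)
    energy       e = sum_ij G(i,j)^2
    homogeneity  h = sum_ij G(i,j) / (1 + |i-j|)

and the per-channel 4-vectors are concatenated in montage order into the
epoch feature vector (60 features for the 15-channel montage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Epoch
from .tfa import TfaConfig, compute_map

#: distance-1 offsets at 0, 45, 90 and 135 degrees (image convention:
#: offset = (d_row, d_col)).
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")


@dataclass
class QuantizedTFM:
    levels: np.ndarray  # integer matrix, entries in 1..L
    L: int


@dataclass
class GLCM:
    G: np.ndarray  # L x L, normalized to unit sum
    L: int
    offsets: tuple
    symmetric: bool


@dataclass
class ChannelFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.contrast, self.correlation,
                         self.energy, self.homogeneity])


@dataclass
class TextureConfig:
    levels: int = 16
    offsets: tuple = DEFAULT_OFFSETS
    symmetric: bool = True
    channels: tuple | None = None  # None = require the epoch's full set
    tfa: TfaConfig = field(default_factory=TfaConfig)


def quantize(values: np.ndarray, L: int) -> QuantizedTFM:
    """Linear min-max quantization of raw (possibly negative) map values
    into L equal-width bins, levels 1..L; a constant map maps to level 1."""
    if L < 2:
        raise ValueError("need at least 2 gray levels")
    v = np.asarray(values, dtype=float)
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return QuantizedTFM(np.ones(v.shape, dtype=np.int64), L)
    lev = np.floor((v - vmin) / (vmax - vmin) * L).astype(np.int64) + 1
    np.clip(lev, 1, L, out=lev)
    return QuantizedTFM(lev, L)


def glcm(q: QuantizedTFM, offsets=DEFAULT_OFFSETS, symmetric: bool = True) -> GLCM:
    """Normalized co-occurrence matrix accumulated over the given offsets.

    For each offset (dr, dc), every in-bounds pixel pair
    (levels[r, c], levels[r+dr, c+dc]) increments one cell; the symmetric
    variant adds the transposed pair as well. Counts over all offsets are
    pooled before normalizing to unit sum.
    """
    if not offsets:
        raise ValueError("offsets must be nonempty")
    lev = q.levels - 1  # 0-based for bincount
    L = q.L
    counts = np.zeros(L * L, dtype=np.int64)
    nrow, ncol = lev.shape
    any_pairs = False
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = lev[r0:r1, c0:c1].ravel()
        b = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts += np.bincount(a * L + b, minlength=L * L)
        any_pairs = True
    if not any_pairs:
        raise ValueError("no offset fits inside the matrix")
    G = counts.reshape(L, L).astype(float)
    if symmetric:
        G = G + G.T
    return GLCM(G / G.sum(), L, tuple(offsets), symmetric)


def contrast(g: GLCM) -> float:
    i, j = np.indices(g.G.shape)
    return float(((i - j) ** 2 * g.G).sum())


def correlation(g: GLCM) -> float:
    """Haralick correlation; returns 0 when either marginal is degenerate
    (single-level image)."""
    G = g.G
    i, j = np.indices(G.shape)
    mu_i = (i * G).sum()
    mu_j = (j * G).sum()
    var_i = ((i - mu_i) ** 2 * G).sum()
    var_j = ((j - mu_j) ** 2 * G).sum()
    if var_i <= 0 or var_j <= 0:
        return 0.0
    cov = ((i - mu_i) * (j - mu_j) * G).sum()
    return float(cov / np.sqrt(var_i * var_j))


def energy(g: GLCM) -> float:
    return float((g.G ** 2).sum())


def homogeneity(g: GLCM) -> float:
    i, j = np.indices(g.G.shape)
    return float((g.G / (1.0 + np.abs(i - j))).sum())


def channel_features(g: GLCM) -> ChannelFeatures:
    return ChannelFeatures(contrast(g), correlation(g), energy(g),
                           homogeneity(g))


def epoch_features(epoch: Epoch, cfg: TextureConfig | None = None) -> np.ndarray:
    """Feature vector of one epoch: per channel, time-frequency map ->
    quantize -> GLCM -> four features, concatenated in channel order.

    Returns a vector of length 4 * n_channels (60 for the full montage).
    """
    cfg = cfg or TextureConfig()
    wanted = cfg.channels if cfg.channels is not None else epoch.channel_names
    index = {name: k for k, name in enumerate(epoch.channel_names)}
    parts = []
    for name in wanted:
        if name not in index:
            raise ValueError(f"epoch is missing channel {name!r}")
        x = epoch.signal[index[name]]
        tfm = compute_map(x, epoch.fs, cfg.tfa)
        # rows = frequency, columns = time for the texture image
        q = quantize(tfm.values.T, cfg.levels)
        g = glcm(q, cfg.offsets, cfg.symmetric)
        parts.append(channel_features(g).as_array())
    return np.concatenate(parts)


def feature_names(channels=None) -> list:
    from .preprocess import DEFAULT_CHANNELS
    channels = channels or DEFAULT_CHANNELS
    return [f"{ch}_{feat}" for ch in channels for feat in FEATURE_NAMES]


def feature_table(epochs, cfg: TextureConfig | None = None):
    """DataFrame of epoch features plus metadata columns
    (subject, t_start, mean_bis, label)."""
    import pandas as pd

    cfg = cfg or TextureConfig()
    rows, meta = [], []
    for ep in epochs:
        rows.append(epoch_features(ep, cfg))
        meta.append((ep.subject_id, ep.t_start, ep.mean_bis, ep.label))
    cols = feature_names(cfg.channels or (epochs[0].channel_names if epochs else None))
    df = pd.DataFrame(np.array(rows), columns=cols)
    md = pd.DataFrame(meta, columns=["subject", "t_start", "mean_bis", "label"])
    return pd.concat([md, df], axis=1)
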