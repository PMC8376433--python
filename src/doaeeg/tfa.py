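"""Cohen-class time-frequency analysis: WVD, pseudo-WVD, smoothed pseudo-WVD.

The Wigner-Ville distribution (WVD) of an analytic signal y(t),

    W(t, f) = \\int y(t + tau/2) y*(t - tau/2) e^{-j 2 pi f tau} dtau,

gives quadratic time-frequency energy density but suffers from oscillatory
cross-terms midway between genuine components. The pseudo-WVD (PWVD) windows
the lag variable with h(tau) (frequency smoothing); the smoothed pseudo-WVD
(SPWVD) additionally convolves over time with g(t) (time smoothing), which is
what actually cancels the time-oscillating cross-terms of parallel tones.
Both windows are rectangular here.

Discretization uses the standard half-lag trick: with y sampled at fs, the
lag product K[n, m] = y[n+m] y*[n-m] corresponds to tau = 2m/fs, so an
n_freqs-point DFT over m yields frequencies f_k = k fs / (2 n_freqs) covering
[0, fs/2). Lag products are truncated at the signal boundaries (no
reflection), and the usable half-lag extent is capped at n_freqs/2 - 1 so
positive and negative lags never collide in the DFT buffer. Values carry a
2/fs scale so that summing a column over frequency (times df) returns the
instantaneous power |y[n]|^2 and total map energy matches signal energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class AnalyticSignal:
    """Complex signal whose imaginary part is the Hilbert transform of the
    real part; its spectrum is one-sided."""

    y: np.ndarray
    fs: float

    def __len__(self):
        return len(self.y)


@dataclass
class TFMap:
    """Discretized time-frequency map.

    ``values`` has shape (n_times, n_freqs); ``kind`` is one of
    {"WVD", "PWVD", "SPWVD", "STFT"}; ``window_lengths`` records
    (h_len, g_len) in samples where applicable.
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    kind: str
    window_lengths: tuple = (None, None)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 1.0

    def energy(self) -> float:
        return float(self.values.sum() * self.dt * self.df)


def analytic_signal(x, fs: float) -> AnalyticSignal:
    """Analytic signal y = x + j H[x] via the FFT-based Hilbert transform."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("x must be a 1-D vector of length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains NaN or Inf")
    return AnalyticSignal(y=sps.hilbert(x), fs=fs)


def _odd(n: int) -> int:
    n = int(round(n))
    return n if n % 2 == 1 else n + 1


def default_h_len(n: int) -> int:
    """Default lag-window length: about a quarter of the epoch, odd."""
    return _odd(n / 4)


def default_g_len(n: int) -> int:
    """Default time-window length: about a sixteenth of the epoch, odd."""
    return _odd(n / 16)


def _box_smooth(K: np.ndarray, g_len: int, idx: np.ndarray) -> np.ndarray:
    """Centered moving average of length g_len along axis 0, evaluated only
    at rows ``idx``; zero-padded at the boundaries (matches truncated-lag
    edge handling)."""
    n = K.shape[0]
    half = g_len // 2
    c = np.cumsum(K, axis=0)
    upper = np.clip(idx + half, 0, n - 1)
    lower = idx - half - 1
    out = c[upper].copy()
    valid = lower >= 0
    out[valid] -= c[lower[valid]]
    return out / g_len


def _quadratic_tfd(y: np.ndarray, fs: float, n_freqs: int,
                   half_lag: int | None, g_len: int | None,
                   time_step: int) -> tuple:
    """Shared WVD/PWVD/SPWVD core. Returns (values, times, freqs)."""
    if n_freqs < 2:
        raise ValueError("n_freqs must be >= 2")
    n = len(y)
    cap = n_freqs // 2 - 1
    if half_lag is None or half_lag > cap:
        half_lag = cap  # frequency resolution caps the usable lag extent
    K = np.zeros((n, n_freqs), dtype=complex)
    K[:, 0] = y * np.conj(y)
    for m in range(1, half_lag + 1):
        # valid times where both n+m and n-m exist (boundary truncation)
        prod = y[2 * m:] * np.conj(y[:n - 2 * m])
        K[m:n - m, m] = prod
        K[m:n - m, n_freqs - m] = np.conj(prod)
    idx = np.arange(0, n, time_step)
    if g_len is not None and g_len > 1:
        K = _box_smooth(K, g_len, idx)
    else:
        K = K[idx]
    W = np.fft.fft(K, axis=1)
    values = (2.0 / fs) * W.real
    resid = np.max(np.abs(W.imag)) if W.size else 0.0
    scale = np.max(np.abs(values)) or 1.0
    if resid * (2.0 / fs) > 1e-8 * scale:
        raise RuntimeError("imaginary residue too large; lag kernel asymmetric")
    times = np.arange(0, n, time_step) / fs
    freqs = np.arange(n_freqs) * fs / (2.0 * n_freqs)
    return values, times, freqs


def wvd(y: AnalyticSignal, n_freqs: int = 256, time_step: int = 1) -> TFMap:
    """Wigner-Ville distribution (no smoothing; full lag support up to the
    frequency-grid cap)."""
    values, times, freqs = _quadratic_tfd(
        y.y, y.fs, n_freqs, half_lag=None, g_len=None, time_step=time_step)
    return TFMap(values, times, freqs, "WVD", (None, None))


def pwvd(y: AnalyticSignal, h_len: int, n_freqs: int = 256,
         time_step: int = 1) -> TFMap:
    """Pseudo-WVD: WVD with a rectangular lag window of ``h_len`` samples."""
    if h_len % 2 == 0:
        raise ValueError("h_len must be odd (symmetric lag window)")
    values, times, freqs = _quadratic_tfd(
        y.y, y.fs, n_freqs, half_lag=(h_len - 1) // 2, g_len=None,
        time_step=time_step)
    return TFMap(values, times, freqs, "PWVD", (h_len, None))


def spwvd(y: AnalyticSignal, h_len: int, g_len: int, n_freqs: int = 256,
          time_step: int = 1) -> TFMap:
    """Smoothed pseudo-WVD: rectangular lag window h plus rectangular time
    window g (normalized to unit sum)."""
    if h_len % 2 == 0 or g_len % 2 == 0:
        raise ValueError("h_len and g_len must be odd (symmetric windows)")
    values, times, freqs = _quadratic_tfd(
        y.y, y.fs, n_freqs, half_lag=(h_len - 1) // 2, g_len=g_len,
        time_step=time_step)
    return TFMap(values, times, freqs, "SPWVD", (h_len, g_len))


def stft_psd(x, fs: float, win_len: int = 256) -> TFMap:
    """Spectrogram (magnitude-squared STFT, density scaling) on the same
    axes convention as the quadratic maps; the cheap comparator."""
    x = np.asarray(x, dtype=float)
    if win_len > len(x):
        raise ValueError("win_len exceeds signal length")
    f, t, S = sps.spectrogram(x, fs=fs, nperseg=win_len,
                              noverlap=win_len // 2)
    return TFMap(S.T.copy(), t, f, "STFT", (win_len, None))


def crop_band(tfm: TFMap, f_lo: float, f_hi: float) -> TFMap:
    """Keep only frequency rows in [f_lo, f_hi] (inclusive).

    EEG under anesthesia carries nearly all its energy below 8 Hz, so the
    pipeline crops maps to [0, 8] Hz before texture analysis.
    """
    if not f_lo < f_hi:
        raise ValueError("require f_lo < f_hi")
    if f_lo > tfm.freqs[-1]:
        raise ValueError("band lies above the frequency grid")
    tol = 1e-9 * max(1.0, abs(f_hi))
    mask = (tfm.freqs >= f_lo - tol) & (tfm.freqs <= f_hi + tol)
    if not mask.any():
        raise ValueError("empty frequency band")
    return TFMap(tfm.values[:, mask].copy(), tfm.times.copy(),
                 tfm.freqs[mask].copy(), tfm.kind, tfm.window_lengths)


@dataclass
class TfaConfig:
    """Time-frequency settings for the feature pipeline.

    ``h_len``/``g_len`` default to about N/4 and N/16 samples (odd) for an
    N-sample epoch; ``time_step`` subsamples the time axis of the map — the
    default gives 0.25 s per pixel at 100 Hz, coarse enough that neighboring
    pixels are not tied together by the time-smoothing window, which keeps
    distance-1 co-occurrence statistics informative.
    """

    kind: str = "spwvd"
    n_freqs: int = 256
    h_len: int | None = None
    g_len: int | None = None
    time_step: int = 25
    f_lo: float = 0.0
    f_hi: float = 8.0
    crop: bool = True


def compute_map(x, fs: float, cfg: TfaConfig) -> TFMap:
    """One channel's map per the config, cropped to the analysis band."""
    kind = cfg.kind.lower()
    n = len(x)
    if kind == "stft":
        tfm = stft_psd(x, fs, min(cfg.n_freqs, n))
    else:
        y = analytic_signal(x, fs)
        h = cfg.h_len if cfg.h_len is not None else default_h_len(n)
        g = cfg.g_len if cfg.g_len is not None else default_g_len(n)
        if kind == "wvd":
            tfm = wvd(y, cfg.n_freqs, cfg.time_step)
        elif kind == "pwvd":
            tfm = pwvd(y, h, cfg.n_freqs, cfg.time_step)
        elif kind == "spwvd":
            tfm = spwvd(y, h, g, cfg.n_freqs, cfg.time_step)
        else:
            raise ValueError(f"unknown map kind {cfg.kind!r}")
    if cfg.crop:
        tfm = crop_band(tfm, cfg.f_lo, cfg.f_hi)
    return tfm
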