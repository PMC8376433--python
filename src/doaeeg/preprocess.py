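"""EEG preprocessing: filtering, decimation, epoch segmentation and BIS labeling.

A raw recording is a multichannel scalp EEG (nominally 1000 Hz, microvolts)
with a parallel bispectral-index (BIS) trace. Cleaning applies, per channel, a
zero-phase band-pass (0.5-70 Hz), a 50 Hz notch for mains interference, and
decimation to 100 Hz with its own anti-aliasing stage. The cleaned recording
is cut into overlapping fixed-length epochs; each epoch inherits the mean BIS
over its span and a three-way depth-of-anesthesia label:

    D (deep hypnotic)       mean BIS < 40
    A (surgical anesthesia) 40 <= mean BIS <= 60
    S (sedation and awake)  mean BIS > 60
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

#: 10/20-montage channel set used throughout (frontal to parietal order).
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8", "P3", "Pz", "P4",
)

LABELS = ("D", "A", "S")


@dataclass
class RawRecording:
    """Multichannel EEG plus a parallel BIS trace.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    fs : float
        EEG sampling rate in Hz.
    channel_names : sequence of str
        One name per row of ``signal``.
    bis : ndarray
        BIS values in [0, 100], sampled at ``bis_fs``.
    bis_fs : float
        BIS sampling rate in Hz (the monitor's own clock).
    subject_id : str
    """

    signal: np.ndarray
    fs: float
    channel_names: tuple = DEFAULT_CHANNELS
    bis: np.ndarray = None
    bis_fs: float = 1.0
    subject_id: str = "unknown"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] < 1:
            raise ValueError("at least one channel required")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")
        if self.bis is not None:
            self.bis = np.asarray(self.bis, dtype=float)
            if np.any((self.bis < 0) | (self.bis > 100)):
                raise ValueError("BIS values must lie in [0, 100]")

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class CleanRecording:
    """Filtered, decimated recording with a record of the applied steps."""

    signal: np.ndarray
    fs: float
    channel_names: tuple
    bis: np.ndarray
    bis_fs: float
    subject_id: str
    provenance: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class Epoch:
    """One fixed-length EEG segment with its depth-of-anesthesia label."""

    signal: np.ndarray  # (n_channels, n_epoch_samples)
    fs: float
    channel_names: tuple
    label: str
    mean_bis: float
    t_start: float
    subject_id: str = "unknown"

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def design_bandpass(fs: float, low: float, high: float, order: int = 4):
    """Second-order sections of the Butterworth band-pass used for cleaning."""
    nyq = fs / 2.0
    if not (0 < low < high):
        raise ValueError(f"require 0 < low < high, got {low}, {high}")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(x, fs: float, low: float = 0.5, high: float = 70.0,
                    order: int = 4):
    """Zero-phase Butterworth band-pass of a single channel.

    Applied forward and backward (``sosfiltfilt``) so the passband has no
    group delay; epoch timing is preserved.
    """
    sos = design_bandpass(fs, low, high, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def design_notch(fs: float, null_freq: float = 50.0, q: float = 30.0):
    if not 0 < null_freq < fs / 2:
        raise ValueError(f"null frequency {null_freq} Hz must be below Nyquist")
    return sps.iirnotch(null_freq, q, fs=fs)


def notch_filter(x, fs: float, null_freq: float = 50.0, q: float = 30.0):
    """Zero-phase IIR notch suppressing mains interference at ``null_freq``."""
    b, a = design_notch(fs, null_freq, q)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def decimate(x, fs_in: float, fs_out: float):
    """Anti-aliased integer-ratio downsampling of one channel.

    The anti-aliasing low-pass (Chebyshev type I, zero phase) sits below the
    new Nyquist ``fs_out / 2`` regardless of what earlier filtering allowed
    through, so out-of-band content cannot fold in. Output length is
    ``floor(len(x) * fs_out / fs_in)``.
    """
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer, got {ratio}")
    q = int(round(ratio))
    x = np.asarray(x, dtype=float)
    if q == 1:
        return x.copy()
    out = sps.decimate(x, q, zero_phase=True)
    n_out = int(np.floor(len(x) * fs_out / fs_in))
    return out[:n_out]


def clean_recording(raw: RawRecording, low: float = 0.5, high: float = 70.0,
                    notch: float | None = 50.0, fs_out: float = 100.0,
                    ) -> CleanRecording:
    """Full per-channel cleaning chain: band-pass, notch, decimate."""
    steps = []
    sig = raw.signal
    out = np.empty_like(sig)
    for c in range(sig.shape[0]):
        out[c] = bandpass_filter(sig[c], raw.fs, low, high)
    steps.append(f"butterworth bandpass {low}-{high} Hz order 4 zero-phase")
    if notch is not None:
        for c in range(out.shape[0]):
            out[c] = notch_filter(out[c], raw.fs, notch)
        steps.append(f"iir notch {notch} Hz Q=30 zero-phase")
    if fs_out != raw.fs:
        dec = np.stack([decimate(out[c], raw.fs, fs_out)
                        for c in range(out.shape[0])])
        steps.append(f"decimate {raw.fs}->{fs_out} Hz (anti-aliased)")
    else:
        dec = out
    return CleanRecording(
        signal=dec, fs=fs_out, channel_names=tuple(raw.channel_names),
        bis=raw.bis, bis_fs=raw.bis_fs, subject_id=raw.subject_id,
        provenance=steps,
    )


def label_epoch(mean_bis: float) -> str:
    """Three-way depth-of-anesthesia label from the epoch-mean BIS.

    Boundary values 40 and 60 map to A: D is "smaller than 40" and S
    "greater than 60", so A takes the closed interval [40, 60].
    """
    if not 0 <= mean_bis <= 100:
        raise ValueError(f"BIS {mean_bis} outside [0, 100]")
    if mean_bis < 40:
        return "D"
    if mean_bis <= 60:
        return "A"
    return "S"


def _mean_bis_over(bis, bis_fs, t0, t1):
    """Mean of the BIS trace over [t0, t1], linearly interpolated onto the
    epoch's own time grid (the monitor clock is not synchronized to EEG)."""
    t_bis = np.arange(len(bis)) / bis_fs
    grid = np.linspace(t0, t1, 61)
    return float(np.mean(np.interp(grid, t_bis, bis)))


def segment_epochs(rec: CleanRecording, epoch_len_s: float = 30.0,
                   overlap_frac: float = 0.5,
                   reject_uv: float | None = 150.0) -> list:
    """Cut a cleaned recording into overlapping labeled epochs.

    Windows start at multiples of ``hop = epoch_len_s * (1 - overlap_frac)``;
    a final window that would overrun the recording is dropped. Epochs whose
    peak absolute amplitude exceeds ``reject_uv`` on any channel are discarded
    (amplitude-threshold artifact rejection; pass ``None`` to disable).
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    n_ep = int(round(epoch_len_s * rec.fs))
    if abs(epoch_len_s * rec.fs - n_ep) > 1e-6:
        raise ValueError("epoch_len_s * fs must be an integer sample count")
    n = rec.signal.shape[1]
    if n < n_ep:
        warnings.warn("recording shorter than one epoch; no epochs produced")
        return []
    hop = int(round(n_ep * (1 - overlap_frac)))
    epochs = []
    for start in range(0, n - n_ep + 1, hop):
        seg = rec.signal[:, start:start + n_ep]
        if reject_uv is not None and np.max(np.abs(seg)) > reject_uv:
            continue
        t0 = start / rec.fs
        mb = _mean_bis_over(rec.bis, rec.bis_fs, t0, t0 + epoch_len_s)
        epochs.append(Epoch(
            signal=seg.copy(), fs=rec.fs, channel_names=rec.channel_names,
            label=label_epoch(mb), mean_bis=mb, t_start=t0,
            subject_id=rec.subject_id,
        ))
    return epochs


def preprocess_recording(raw: RawRecording, epoch_len_s: float = 30.0,
                         overlap_frac: float = 0.5, fs_out: float = 100.0,
                         reject_uv: float | None = 150.0) -> list:
    """Convenience chain: clean, decimate, segment, label."""
    rec = clean_recording(raw, fs_out=fs_out)
    return segment_epochs(rec, epoch_len_s, overlap_frac, reject_uv)
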