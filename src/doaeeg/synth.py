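"""Seeded generator of EEG-like multichannel recordings for the three
anesthesia states.

Real operating-room recordings for this problem are not publicly
distributable, so the pipeline is exercised on synthetic 15-channel signals
whose per-class spectral content follows the qualitative picture of
anesthetic EEG: under deep hypnosis rhythms below 2 Hz dominate; during
surgical anesthesia there is broad, strong activity across 0-8 Hz; in
sedation/awake the activity is intermediate with some faster (8-20 Hz)
content. Each channel is a random mixture of shared band-limited sources
(giving realistic inter-channel correlation) plus independent pink (1/f)
background noise and an optional 50 Hz mains contaminant, scaled to a
physiologic ~100 microvolt amplitude range. A parallel BIS trace is drawn
inside the class's own BIS bracket so the BIS-derived epoch labels are
consistent by construction.

What this generator does NOT emulate: drug kinetics, state transitions
inside a recording, eye-blink/EMG artifacts, electrode drift, or volume-
conduction physics. Results on it demonstrate pipeline correctness and
class-recovery capacity, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import DEFAULT_CHANNELS, RawRecording, preprocess_recording


@dataclass
class ClassProfile:
    """Spectral recipe for one anesthesia state.

    ``bands`` maps (f_lo, f_hi) in Hz to an amplitude gain relative to the
    unit-variance pink background; ``bis_range`` must sit inside the
    label's BIS bracket (D < 40, A in [40, 60], S > 60).
    """

    label: str
    bands: dict = field(default_factory=dict)
    bis_range: tuple = (45.0, 58.0)
    amplitude_uv: float = 85.0  # target 99th-percentile |value|
    line_noise_uv: float = 3.0  # 50 Hz contaminant before normalization
    pink_gain: float = 1.0  # 1/f background level (slow-wave drift)

    def __post_init__(self):
        brackets = {"D": (0.0, 40.0), "A": (40.0, 60.0), "S": (60.0, 100.0)}
        if self.label not in brackets:
            raise ValueError(f"unknown label {self.label!r}")
        lo, hi = brackets[self.label]
        if not (lo <= self.bis_range[0] <= self.bis_range[1] <= hi):
            raise ValueError(f"bis_range {self.bis_range} outside the "
                             f"{self.label} bracket {lo}-{hi}")
        if any(g < 0 for g in self.bands.values()):
            raise ValueError("band gains must be nonnegative")


#: Default state recipes. D: dominant slow (< 2 Hz) rhythms over a full 1/f
#: background; A: strong, broad delta-theta activity (split into a lower and
#: an upper band source so the whole 0-8 Hz range is occupied); S:
#: intermediate 2-8 Hz activity with weak faster (8-20 Hz) content and a
#: reduced 1/f background (lighter anesthesia carries less slow-wave drift).
DEFAULT_PROFILES = {
    "D": ClassProfile("D", bands={(0.5, 2.0): 3.0}, bis_range=(22.0, 38.0)),
    "A": ClassProfile("A", bands={(0.5, 4.0): 1.8, (4.0, 8.0): 1.2},
                      bis_range=(44.0, 58.0)),
    "S": ClassProfile("S", bands={(2.0, 8.0): 1.0, (8.0, 20.0): 0.5},
                      bis_range=(64.0, 85.0), pink_gain=0.5),
}


def _band_source(rng, n, fs, f_lo, f_hi):
    """Unit-variance band-limited Gaussian noise via spectral masking."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = np.zeros(len(freqs), dtype=complex)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    k = int(mask.sum())
    spec[mask] = rng.normal(size=k) + 1j * rng.normal(size=k)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng, n, fs, f_floor=0.1):
    """Unit-variance 1/f-amplitude noise (flat below ``f_floor``)."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_floor))
    amp[0] = 0.0
    spec = amp * (rng.normal(size=len(freqs)) + 1j * rng.normal(size=len(freqs)))
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_recording(profile: ClassProfile, duration: float = 120.0,
                       fs: float = 1000.0, n_channels: int = 15,
                       seed: int = 0, bis_fs: float = 1.0,
                       n_sources_per_band: int = 2,
                       mix_jitter: tuple = (0.8, 1.2)) -> RawRecording:
    """One seeded multichannel recording for a single anesthesia state."""
    if duration < 30:
        raise ValueError("duration must cover at least one 30 s epoch")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    # shared oscillatory sources, mixed into channels with random loadings
    sources, gains = [], []
    for (f_lo, f_hi), gain in profile.bands.items():
        for _ in range(n_sources_per_band):
            sources.append(_band_source(rng, n, fs, f_lo, f_hi))
            gains.append(gain)
    sig = np.empty((n_channels, n))
    t = np.arange(n) / fs
    line = np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    shared = np.sqrt(0.5)  # half the band variance is common across channels
    bands = [b for b in profile.bands for _ in range(n_sources_per_band)]
    for c in range(n_channels):
        x = profile.pink_gain * _pink_noise(rng, n, fs)
        for (s, g), band in zip(zip(sources, gains), bands):
            private = _band_source(rng, n, fs, *band)
            comp = shared * s + np.sqrt(1 - shared ** 2) * private
            x = x + g * rng.uniform(*mix_jitter) * comp
        x = x + profile.line_noise_uv / profile.amplitude_uv * line
        p99 = np.percentile(np.abs(x), 99)
        sig[c] = x * (profile.amplitude_uv / p99)
    # BIS: constant level inside the class bracket plus monitor jitter
    n_bis = max(2, int(round(duration * bis_fs)))
    level = rng.uniform(*profile.bis_range)
    bis = level + rng.normal(0, 1.0, n_bis)
    bis = np.clip(bis, profile.bis_range[0], profile.bis_range[1])
    names = tuple(DEFAULT_CHANNELS[:n_channels]) if n_channels <= 15 else \
        tuple(f"ch{i}" for i in range(n_channels))
    return RawRecording(signal=sig, fs=fs, channel_names=names, bis=bis,
                        bis_fs=bis_fs, subject_id=f"synth-{profile.label}-{seed}")


def generate_dataset(n_per_class: int = 60, duration: float = 120.0,
                     fs: float = 1000.0, seed: int = 0,
                     profiles: dict | None = None,
                     n_channels: int = 15) -> tuple:
    """Balanced three-class epoch set, preprocessed and ready for feature
    extraction. Returns (epochs, labels array).

    Recordings are generated per class with seeds spawned from ``seed``
    until ``n_per_class`` epochs survive preprocessing.
    """
    profiles = profiles or DEFAULT_PROFILES
    root = np.random.SeedSequence(seed)
    epochs, labels = [], []
    for label in ("D", "A", "S"):
        prof = profiles[label]
        collected = []
        child = root.spawn(1)[0]
        tries = 0
        while len(collected) < n_per_class:
            sub_seed = int(child.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            rec = generate_recording(prof, duration, fs, n_channels,
                                     seed=sub_seed)
            collected.extend(preprocess_recording(rec))
            tries += 1
            if tries > 10 * (1 + n_per_class):
                raise RuntimeError("artifact rejection discarded too many epochs")
        collected = collected[:n_per_class]
        epochs.extend(collected)
        labels.extend([label] * n_per_class)
    return epochs, np.array(labels)


def dataset_manifest(epochs):
    """Per-epoch provenance table (subject, start time, mean BIS, label)."""
    import pandas as pd

    return pd.DataFrame(
        [(ep.subject_id, ep.t_start, ep.mean_bis, ep.label) for ep in epochs],
        columns=["subject", "t_start", "mean_bis", "label"],
    )
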