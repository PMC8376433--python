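"""Readers and writers for recordings and epoch stores.

Recordings arrive either as EDF files (channel labels matched
case-insensitively against the 15-channel montage) or as wide CSV tables
with one column per channel plus a ``bis`` column sampled on the EEG clock.
Epoch sets persist as a single NPZ bundle (signals stacked) with a sidecar
CSV of per-epoch metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_CHANNELS, Epoch, RawRecording


def read_csv_recording(path, fs: float = 1000.0, subject_id: str | None = None,
                       channels=DEFAULT_CHANNELS) -> RawRecording:
    """Wide CSV: one column per channel plus a ``bis`` column (header
    required); every column is sampled at ``fs``."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    missing = [ch for ch in channels if ch.lower() not in cols]
    if missing:
        raise ValueError(f"CSV is missing channel columns {missing}")
    if "bis" not in cols:
        raise ValueError("CSV must contain a 'bis' column")
    sig = np.stack([df[cols[ch.lower()]].to_numpy(dtype=float)
                    for ch in channels])
    return RawRecording(
        signal=sig, fs=fs, channel_names=tuple(channels),
        bis=df[cols["bis"]].to_numpy(dtype=float), bis_fs=fs,
        subject_id=subject_id or Path(path).stem,
    )


def write_csv_recording(rec: RawRecording, path) -> None:
    if rec.bis_fs != rec.fs:
        t_eeg = np.arange(rec.signal.shape[1]) / rec.fs
        t_bis = np.arange(len(rec.bis)) / rec.bis_fs
        bis = np.interp(t_eeg, t_bis, rec.bis)
    else:
        bis = rec.bis
    df = pd.DataFrame({ch: rec.signal[i] for i, ch in enumerate(rec.channel_names)})
    df["bis"] = bis
    df.to_csv(path, index=False)


def read_edf_recording(path, channels=DEFAULT_CHANNELS, bis_channel: str = "bis",
                       subject_id: str | None = None) -> RawRecording:
    """EDF reader (requires ``mne``); channel labels matched
    case-insensitively, with a BIS trace either as an EDF channel named
    ``bis_channel`` or absent (bis then defaults to zeros)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    lookup = {name.lower(): name for name in raw.ch_names}
    missing = [ch for ch in channels if ch.lower() not in lookup]
    if missing:
        raise ValueError(f"EDF is missing channels {missing}")
    data = raw.get_data(picks=[lookup[ch.lower()] for ch in channels])
    fs = float(raw.info["sfreq"])
    if bis_channel.lower() in lookup:
        bis = raw.get_data(picks=[lookup[bis_channel.lower()]])[0]
        bis = np.clip(bis, 0, 100)
    else:
        bis = np.zeros(int(data.shape[1] / fs) + 1)
    return RawRecording(
        signal=data * 1e6 if np.abs(data).max() < 0.05 else data,  # V -> uV
        fs=fs, channel_names=tuple(channels), bis=bis,
        bis_fs=fs if bis_channel.lower() in lookup else 1.0,
        subject_id=subject_id or Path(path).stem,
    )


def save_epochs(epochs, out_dir) -> None:
    """NPZ bundle of stacked epoch signals + sidecar metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sig = np.stack([ep.signal for ep in epochs])
    np.savez(out / "epochs.npz", signal=sig,
             fs=np.array([epochs[0].fs]),
             channel_names=np.array(epochs[0].channel_names))
    meta = pd.DataFrame(
        [(ep.subject_id, ep.t_start, ep.mean_bis, ep.label) for ep in epochs],
        columns=["subject", "t_start", "mean_bis", "label"],
    )
    meta.to_csv(out / "epochs_meta.csv", index=False)


def load_epochs(in_dir) -> list:
    src = Path(in_dir)
    with np.load(src / "epochs.npz", allow_pickle=False) as bundle:
        sig = bundle["signal"]
        fs = float(bundle["fs"][0])
        names = tuple(str(c) for c in bundle["channel_names"])
    meta = pd.read_csv(src / "epochs_meta.csv")
    return [
        Epoch(signal=sig[i], fs=fs, channel_names=names,
              label=row.label, mean_bis=float(row.mean_bis),
              t_start=float(row.t_start), subject_id=str(row.subject))
        for i, row in enumerate(meta.itertuples())
    ]
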