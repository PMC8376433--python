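"""Shared fixtures. The expensive synthetic-dataset feature extractions are
session-scoped so the end-to-end tests share one computation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")

from doaeeg.evaluate import CVConfig
from doaeeg.synth import DEFAULT_PROFILES, ClassProfile, generate_dataset
from doaeeg.texture import TextureConfig, feature_table


def extract_features(epochs):
    df = feature_table(epochs, TextureConfig())
    X = df.drop(columns=["subject", "t_start", "mean_bis", "label"]).to_numpy()
    return X, df["label"].to_numpy()


@pytest.fixture(scope="session")
def default_dataset_features():
    """Feature matrix of the default 60-epochs-per-class synthetic set."""
    epochs, labels = generate_dataset(n_per_class=60, seed=7)
    X, y = extract_features(epochs)
    assert (y == labels).all()
    return X, y


@pytest.fixture(scope="session")
def identical_profile_features():
    """Feature matrix of a set where all three classes share one spectral
    profile (class structure destroyed; only BIS labels differ).

    Each 30 s recording contributes exactly one epoch so that no
    recording-level fingerprint (shared gain draws, overlapping samples)
    ties an epoch to its class; what remains is pure spectral information,
    of which there is none here.
    """
    a = DEFAULT_PROFILES["A"]
    profiles = {
        "D": ClassProfile("D", bands=dict(a.bands), bis_range=(22.0, 38.0),
                          pink_gain=a.pink_gain),
        "A": ClassProfile("A", bands=dict(a.bands), bis_range=(44.0, 58.0),
                          pink_gain=a.pink_gain),
        "S": ClassProfile("S", bands=dict(a.bands), bis_range=(64.0, 85.0),
                          pink_gain=a.pink_gain),
    }
    epochs, _ = generate_dataset(n_per_class=20, duration=30.0, seed=7,
                                 profiles=profiles)
    return extract_features(epochs)


@pytest.fixture
def default_cv_config():
    return CVConfig(seed=7)
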