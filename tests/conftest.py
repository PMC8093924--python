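"""Shared fixtures for the srcflow test suite."""

import numpy as np
import pandas as pd
import pytest

from srcflow import density, synthio


def make_epochs(
    n_sources=2,
    n_samples=1000,
    n_trials=40,
    fs=250.0,
    seed=0,
    subject_id="s0",
    activations=None,
):
    """White-noise SourceEpochs helper with sensible metadata."""
    rng = np.random.default_rng(seed)
    if activations is None:
        activations = rng.standard_normal((n_sources, n_samples, n_trials))
    n_sources = activations.shape[0]
    epoch_ms = activations.shape[1] * 1000.0 / fs
    return synthio.SourceEpochs(
        subject_id=subject_id,
        activations=activations,
        fs=fs,
        dipole_mni=rng.uniform(-40, 40, (n_sources, 3)),
        variance_rank=np.arange(1, n_sources + 1),
        epoch_window=(-epoch_ms / 2.0, epoch_ms / 2.0),
    )


@pytest.fixture(scope="session")
def white_epochs_250():
    """2 sources x 4 s x 60 trials of unit white noise at 250 Hz."""
    return make_epochs(n_sources=2, n_samples=1000, n_trials=60, fs=250.0, seed=11)


@pytest.fixture(scope="session")
def tiny_parcellation():
    """12-ROI synthetic parcellation at 8 mm (fast to build and query)."""
    return density.synthetic_parcellation(12, 8.0, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    return synthio.generate_cohort(8, 10, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trials(correct, rt, condition=None):
    """Trial table from explicit per-trial vectors."""
    n = len(correct)
    if condition is None:
        condition = ["incongruent"] * n
    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "condition": condition,
            "correct": np.asarray(correct, dtype=bool),
            "rt": np.asarray(rt, dtype=float),
        }
    )
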