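"""Shared fixtures: small synthetic datasets reused across test modules.

Heavy signal generation is session-scoped so statistical checks share
one dataset instead of regenerating it per test.  The reduced problem
sizes (128 Hz, tens of epochs per stage) keep the suite fast while
leaving every statistical margin comfortably wide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plvsleep.bands import BAND_ORDER, CANONICAL_BANDS, STAGE_ORDER
from plvsleep.connectivity import epochset_plv_matrices, plv_feature_table
from plvsleep.preprocessing import filter_bank
from plvsleep.synthetic import GeneratorConfig, synth_dataset

TEST_FS = 128.0


@pytest.fixture(scope="session")
def default_dataset():
    """Default stage-contrast dataset: 40 epochs/stage, 12 ch, 128 Hz."""
    config = GeneratorConfig(epochs_per_stage=40, sampling_rate=TEST_FS, seed=11)
    return synth_dataset(config)


@pytest.fixture(scope="session")
def default_band_epochs(default_dataset):
    return filter_bank(default_dataset, CANONICAL_BANDS)


@pytest.fixture(scope="session")
def default_band_matrices(default_band_epochs):
    """Per-band stacks of per-epoch PLV matrices plus the shared labels."""
    mats = {band: epochset_plv_matrices(default_band_epochs[band])
            for band in BAND_ORDER}
    labels = default_band_epochs["delta"].labels
    return mats, labels


@pytest.fixture(scope="session")
def default_features(default_band_epochs) -> pd.DataFrame:
    return plv_feature_table(default_band_epochs)


def synthetic_feature_frame(rng: np.random.Generator, n_per_stage: int = 20,
                            n_channels: int = 12,
                            shift: dict | None = None) -> pd.DataFrame:
    """Cheap direct-construction feature table (no signal synthesis).

    Gaussian features per (band, pair); ``shift[(band, stage)]`` adds a
    mean offset to every pair feature of that band for that stage.
    """
    shift = shift or {}
    n_pairs = n_channels * (n_channels - 1) // 2
    cols = [f"{i}-{j}" for i in range(n_channels) for j in range(i + 1, n_channels)]
    frames = []
    stages = np.repeat(STAGE_ORDER, n_per_stage)
    for band in BAND_ORDER:
        x = 0.5 + 0.05 * rng.standard_normal((len(stages), n_pairs))
        for k, stage in enumerate(stages):
            x[k] += shift.get((band, stage), 0.0)
        df = pd.DataFrame(x, columns=cols)
        df.insert(0, "epoch", np.arange(len(stages)))
        df.insert(1, "stage", stages)
        df.insert(2, "band", band)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
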