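"""Shared fixtures: one synthetic dataset and fitted detector per session."""

import numpy as np
import pytest

import seizureloop as sl

CANONICAL_SEED = 1


@pytest.fixture(scope="session")
def default_config():
    return sl.GeneratorConfig(seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def recording(default_config):
    return sl.generate_recording(default_config)


@pytest.fixture(scope="session")
def epoch_dataset(default_config):
    """100 seizure + 100 non-seizure labeled 3-s epochs at 125 Hz."""
    return sl.generate_epoch_dataset(100, 100, 3.0, config=default_config)


@pytest.fixture(scope="session")
def split(epoch_dataset):
    return sl.balanced_subsample_and_split(epoch_dataset, 100, 0.8,
                                           seed=CANONICAL_SEED)


@pytest.fixture(scope="session")
def fitted_model(split):
    """Threshold model + normalization fitted on the training split."""
    train_table = sl.feature_table(split.train)
    norm = sl.fit_normalization(train_table)
    normed = sl.apply_normalization(train_table, norm)
    model = sl.fit_thresholds(normed[normed.label == sl.SEIZURE],
                              normalized=True, fs=125.0)
    return model, norm


@pytest.fixture(scope="session")
def online_model():
    """Threshold model fitted the way the online system is deployed: on
    filtered, window-segmented training data (labels via the majority-
    overlap rule), so streaming decisions see the same feature scale."""
    rec = sl.generate_recording(
        sl.GeneratorConfig(seed=CANONICAL_SEED + 100, n_seizures=8))
    epochs = sl.segment(sl.iir_filter(rec), 3.0)
    table = sl.feature_table(epochs)
    norm = sl.fit_normalization(table)
    normed = sl.apply_normalization(table, norm)
    model = sl.fit_thresholds(normed[normed.label == sl.SEIZURE],
                              normalized=True, fs=125.0)
    return model, norm


@pytest.fixture()
def rng():
    return np.random.default_rng(CANONICAL_SEED)
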