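import numpy as np
import pandas as pd
import pytest

from pingdecode.containers import EpochedEEG, FeatureSeries
from pingdecode.design import generate_design, make_pseudo_pings
from pingdecode.simulate import SimulationConfig, simulate_epochs


@pytest.fixture(scope="session")
def default_design():
    return generate_design(seed=11)


@pytest.fixture(scope="session")
def small_design():
    """2 blocks x 4 pairs x 4 reps = 32 recall trials."""
    return generate_design(n_blocks=2, n_pairs_per_block=4, n_reps=4, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_channels=8, seed=3, tmin_ms=-400.0, tmax_ms=1600.0)


@pytest.fixture(scope="session")
def small_epochs(small_design, small_config):
    return simulate_epochs(small_design, small_config, lock="cue")


@pytest.fixture(scope="session")
def ping_locked_epochs(small_design, small_config):
    design = make_pseudo_pings(small_design, seed=9)
    return simulate_epochs(design, small_config, lock="ping")


def make_epochs(data, sfreq=250.0, tmin=-200.0, ch_names=None, metadata=None,
                lock="cue"):
    """Build an EpochedEEG around a raw array for focused feature tests."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_times = data.shape
    times = tmin + np.arange(n_times) * (1000.0 / sfreq)
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(n_ch)]
    if metadata is None:
        metadata = pd.DataFrame({"trial_id": np.arange(n_trials)})
    return EpochedEEG(data, times, sfreq, list(ch_names), metadata, lock)


def make_features(values, step_ms=20.0, metadata=None):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.shape[2], dtype=float) * step_ms
    return FeatureSeries(values, times,
                         [f"f{i}" for i in range(values.shape[1])],
                         metadata=metadata)


def class_pattern_features(rng, n_trials=60, n_channels=8, n_windows=10,
                           signal_windows=(6, 7, 8), effect=2.0, n_classes=2):
    """Gaussian features with class-specific patterns in selected windows."""
    labels = np.repeat(np.arange(n_classes), n_trials // n_classes)
    X = rng.standard_normal((labels.size, n_channels, n_windows))
    patterns = rng.standard_normal((n_classes, n_channels))
    patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
    for w in signal_windows:
        if w < n_windows:
            X[:, :, w] += effect * patterns[labels]
    return make_features(X), labels
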