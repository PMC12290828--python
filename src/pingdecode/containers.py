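"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["POSTERIOR_CHANNELS", "CHANNELS_10_20", "EpochedEEG", "FeatureSeries",
           "DecodingTimecourse"]

#: occipitoparietal channel set used for ERP trace averaging
POSTERIOR_CHANNELS = (
    "C3", "C4", "P3", "P4", "O1", "O2", "Cz", "Pz", "Oz", "CP1", "CP2",
    "C1", "C2", "P1", "P2", "CP3", "CP4", "PO3", "PO4", "PO7", "PO8",
    "CPz", "POz",
)

#: 64 channel names from the extended international 10-20 system. Posterior
#: channels come first so that simulations with few channels still contain the
#: full ERP set.
CHANNELS_10_20 = POSTERIOR_CHANNELS + (
    "Fp1", "Fp2", "Fpz", "AF3", "AF4", "AF7", "AF8",
    "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "Fz",
    "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FCz", "FT7", "FT8",
    "T7", "T8", "C5", "C6", "TP7", "TP8", "TP9", "TP10",
    "P5", "P6", "P7", "P8", "PO9", "PO10", "O9", "O10",
)
assert len(CHANNELS_10_20) == 64 and len(set(CHANNELS_10_20)) == 64


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG: a trial x channel x time tensor.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Voltages in microvolt (float32).
    times : ndarray
        Sample times in ms relative to the lock event; uniform spacing
        1000/sfreq.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
    metadata : pandas.DataFrame
        Trial table row-aligned with ``data``.
    lock : str
        Event defining t = 0: 'cue', 'ping', 'pseudo_ping' or
        'encoding_image'.
    seed : int or None
        Seed of the simulation that produced the data, if any.
    """

    data: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    sfreq: float
    ch_names: list[str]
    metadata: pd.DataFrame = field(repr=False)
    lock: str = "cue"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match times")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows do not match trial axis")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochedEEG":
        return EpochedEEG(self.data.copy(), self.times.copy(), self.sfreq,
                          list(self.ch_names), self.metadata.copy(), self.lock,
                          self.seed)

    def select_trials(self, mask) -> "EpochedEEG":
        """Subset trials by boolean mask or integer indices."""
        idx = np.asarray(mask)
        return EpochedEEG(self.data[idx], self.times.copy(), self.sfreq,
                          list(self.ch_names), self.metadata.iloc[idx].reset_index(drop=True),
                          self.lock, self.seed)

    def channel_indices(self, names: Sequence[str]) -> np.ndarray:
        unknown = [n for n in names if n not in self.ch_names]
        if unknown:
            raise ValueError(f"unknown channel names: {unknown}")
        lookup = {n: i for i, n in enumerate(self.ch_names)}
        return np.asarray([lookup[n] for n in names])

    def to_mne(self):
        """Convert to an :class:`mne.EpochsArray` (requires mne)."""
        import mne  # optional dependency

        info = mne.create_info(list(self.ch_names), self.sfreq, ch_types="eeg")
        # mne expects volts and seconds
        return mne.EpochsArray(self.data.astype(float) * 1e-6, info,
                               tmin=self.times[0] / 1000.0, verbose="error")


@dataclass
class FeatureSeries:
    """Classifier features: a trial x feature x window tensor.

    ``window_times`` are window-centre latencies in ms; ``provenance``
    records whether features are windowed voltages or Hilbert band power.
    """

    values: np.ndarray = field(repr=False)
    window_times: np.ndarray = field(repr=False)
    feature_names: list[str]
    provenance: str = "voltage"
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_times = np.asarray(self.window_times, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_trials, n_features, n_windows)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature axis does not match feature_names")
        if self.values.shape[2] != self.window_times.size:
            raise ValueError("window axis does not match window_times")
        if self.window_times.size > 1 and not (np.diff(self.window_times) > 0).all():
            raise ValueError("window_times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]

    def copy(self) -> "FeatureSeries":
        return FeatureSeries(self.values.copy(), self.window_times.copy(),
                             list(self.feature_names), self.provenance,
                             None if self.metadata is None else self.metadata.copy())

    def window_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask of windows with centres in [start_ms, end_ms]."""
        return (self.window_times >= start_ms) & (self.window_times <= end_ms)


@dataclass
class DecodingTimecourse:
    """Time-resolved decoding result.

    ``empirical`` is the metric per window — shape (n_windows,) for a single
    participant or (n_participants, n_windows) for a group. ``shuffled`` holds
    the first-level label-shuffle distribution with one extra leading
    permutation axis, or None when no shuffles were run.
    """

    window_times: np.ndarray = field(repr=False)
    empirical: np.ndarray = field(repr=False)
    shuffled: np.ndarray | None = field(default=None, repr=False)
    metric: str = "auc"
    chance: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        self.window_times = np.asarray(self.window_times, dtype=float)
        self.empirical = np.asarray(self.empirical, dtype=float)
        if self.empirical.shape[-1] != self.window_times.size:
            raise ValueError("empirical window axis does not match window_times")
        if self.shuffled is not None:
            self.shuffled = np.asarray(self.shuffled, dtype=float)
            if self.shuffled.shape[-1] != self.window_times.size:
                raise ValueError("shuffled window axis does not match window_times")

    def replace(self, **kw) -> "DecodingTimecourse":
        return replace(self, **kw)
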