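"""Feature extraction: baseline correction, Gaussian-weighted windowed
downsampling, cross-channel z-scoring, and Hilbert band power.

The decoding features are either windowed voltages or band-power envelopes.
Voltages are downsampled from the acquisition rate to 50 Hz by a moving
window (140 ms long, stepping 20 ms) whose samples are combined with a
Gaussian-weighted mean: the centre sample gets weight 1 and the samples at
the window edge get weight ``tail_weight`` (0.15); weights are normalised to
sum to one. The Gaussian's sigma is solved from the tail-weight condition
exp(-e^2 / (2 sigma^2)) = tail_weight with e the half-window extent in ms,
which realises a FWHM of ~82 ms. Per window, feature vectors are z-scored
across channels (population SD) so classifiers see pattern shape, not global
amplitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .containers import EpochedEEG, FeatureSeries

__all__ = ["WindowSpec", "BandSpec", "baseline_correct", "gaussian_moving_average",
           "zscore_across_channels", "hilbert_band_power"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Windowed-downsampling parameters (ms)."""

    length_ms: float = 140.0
    step_ms: float = 20.0
    center_weight: float = 1.0
    tail_weight: float = 0.15

    def __post_init__(self) -> None:
        if not self.length_ms >= self.step_ms > 0:
            raise ValueError("require length_ms >= step_ms > 0")
        if not 0 < self.tail_weight <= self.center_weight:
            raise ValueError("require 0 < tail_weight <= center_weight")


@dataclass(frozen=True)
class BandSpec:
    """Named frequency bands in Hz."""

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "theta": (3.0, 7.0),
        "alpha": (8.0, 12.0),
        "beta": (13.0, 30.0),
        "gamma": (35.0, 80.0),
    })

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r} is degenerate: ({lo}, {hi})")

    def validate_sfreq(self, sfreq: float) -> None:
        for name, (_, hi) in self.bands.items():
            if hi >= sfreq / 2:
                raise ValueError(
                    f"band {name!r} upper edge {hi} Hz is at or above the "
                    f"Nyquist frequency {sfreq / 2} Hz"
                )


def baseline_correct(epochs: EpochedEEG,
                     window: tuple[float, float] = (-200.0, 0.0)) -> EpochedEEG:
    """Subtract, per trial and channel, the mean over the half-open baseline
    window ``[start, end)`` (default the 200 ms before the lock event)."""
    start, end = window
    if not start < end <= 0:
        raise ValueError("baseline window must satisfy start < end <= 0")
    mask = (epochs.times >= start) & (epochs.times < end)
    if not mask.any():
        raise ValueError(
            f"baseline window [{start}, {end}) ms lies outside the epoch "
            f"[{epochs.times[0]}, {epochs.times[-1]}] ms"
        )
    out = epochs.copy()
    base = out.data[:, :, mask].mean(axis=2, keepdims=True)
    out.data = (out.data - base).astype(epochs.data.dtype)
    return out


def gaussian_kernel(spec: WindowSpec, sfreq: float) -> tuple[np.ndarray, int]:
    """Normalised Gaussian window weights and the half-window size in samples."""
    dt = 1000.0 / sfreq
    half = int(np.floor(spec.length_ms / 2.0 / dt))
    if half < 1:
        raise ValueError("window shorter than two samples at this sampling rate")
    offsets = np.arange(-half, half + 1) * dt
    e = half * dt
    sigma = e / np.sqrt(2.0 * np.log(spec.center_weight / spec.tail_weight))
    w = spec.center_weight * np.exp(-(offsets ** 2) / (2.0 * sigma ** 2))
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
    logger.debug("Gaussian window: sigma=%.2f ms, realized FWHM=%.2f ms", sigma, fwhm)
    return w / w.sum(), half


def gaussian_moving_average(epochs: EpochedEEG,
                            spec: WindowSpec = WindowSpec()) -> FeatureSeries:
    """Windowed downsampling with a Gaussian-weighted mean.

    One output per ``step_ms``; only windows fully inside the epoch are
    emitted, so the output count is floor((n_times - window)/step) + 1 and the
    output rate is 1000/step_ms Hz (50 Hz at the defaults).
    """
    w, half = gaussian_kernel(spec, epochs.sfreq)
    n_win = 2 * half + 1
    if n_win > epochs.n_times:
        raise ValueError(
            f"window of {n_win} samples longer than the epoch ({epochs.n_times} samples)"
        )
    step = max(1, int(round(spec.step_ms * epochs.sfreq / 1000.0)))
    views = np.lib.stride_tricks.sliding_window_view(epochs.data, n_win, axis=2)
    values = views[:, :, ::step, :].astype(float) @ w
    centers = np.arange(half, epochs.n_times - half, step)
    return FeatureSeries(values, epochs.times[centers], list(epochs.ch_names),
                         provenance="voltage", metadata=epochs.metadata.copy())


def zscore_across_channels(fs: FeatureSeries) -> FeatureSeries:
    """Z-score each (trial, window) feature vector across features.

    Uses the population (n) denominator. A zero-variance vector is mapped to
    all zeros with a warning rather than NaN, so degenerate inputs cannot
    poison the pipeline.
    """
    if fs.n_features < 2:
        raise ValueError("z-scoring across channels needs at least 2 features")
    mean = fs.values.mean(axis=1, keepdims=True)
    sd = fs.values.std(axis=1, keepdims=True)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} (trial, window) vectors have zero variance; "
            "set to zeros", stacklevel=2)
        sd = np.where(zero, 1.0, sd)
    out = fs.copy()
    out.values = (fs.values - mean) / sd
    out.values[np.broadcast_to(zero, out.values.shape)] = 0.0
    return out


def _bandpass_sos(lo: float, hi: float, sfreq: float, order: int = 4):
    return butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")


def hilbert_band_power(epochs: EpochedEEG, bands: BandSpec = BandSpec(),
                       window: WindowSpec = WindowSpec(), order: int = 4,
                       zscore: bool = True) -> FeatureSeries:
    """Per-channel band power via the Hilbert transform.

    Each band is band-pass filtered (zero-phase two-pass Butterworth of the
    given order), the analytic-signal envelope squared to power, and the
    result sent down the same windowing (and optionally z-scoring) path as
    the voltage features. Feature count is n_channels x n_bands.
    """
    bands.validate_sfreq(epochs.sfreq)
    pieces = []
    names = []
    for band_name, (lo, hi) in bands.bands.items():
        sos = _bandpass_sos(lo, hi, epochs.sfreq, order)
        filtered = sosfiltfilt(sos, epochs.data.astype(float), axis=2)
        power = np.abs(hilbert(filtered, axis=2)) ** 2
        pieces.append(power)
        names.extend(f"{ch}_{band_name}" for ch in epochs.ch_names)
    stacked = np.concatenate(pieces, axis=1)
    pseudo = EpochedEEG(stacked, epochs.times, epochs.sfreq, names,
                        epochs.metadata, epochs.lock, epochs.seed)
    fs = gaussian_moving_average(pseudo, window)
    fs.provenance = "band-power"
    if zscore:
        fs = zscore_across_channels(fs)
        fs.provenance = "band-power"
    return fs
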