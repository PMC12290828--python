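"""Event-related potentials and the ping vs no-ping amplitude contrast.

Pings flash a high-contrast bullseye during retrieval and should evoke a
robust posterior visual response, peaking roughly 200-300 ms after the ping.
``erp_average`` produces condition-mean traces (band-passed 0.2-40 Hz,
baseline-corrected) averaged over the posterior channel set;
``ping_contrast`` tests, channel by channel, whether mean amplitude 200-400
ms after (pseudo-)pings is larger on pinged trials, using a Monte-Carlo
permutation across participants with Bonferroni correction over channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .containers import POSTERIOR_CHANNELS, EpochedEEG
from .features import baseline_correct

__all__ = ["ERPResult", "erp_average", "ping_contrast"]


@dataclass
class ERPResult:
    """Condition-mean traces and/or the per-channel contrast."""

    times: np.ndarray | None = field(default=None, repr=False)
    traces: dict[str, np.ndarray] | None = field(default=None, repr=False)      # condition -> (C, T)
    posterior_traces: pd.DataFrame | None = field(default=None, repr=False)     # time x condition
    contrast: pd.DataFrame | None = field(default=None, repr=False)             # per channel
    n_randomizations: int | None = None


def _bandpass(data: np.ndarray, sfreq: float, band: tuple[float, float],
              order: int = 4) -> np.ndarray:
    sos = butter(order, band, btype="bandpass", fs=sfreq, output="sos")
    return sosfiltfilt(sos, data.astype(float), axis=-1)


def erp_average(epochs: EpochedEEG, band: tuple[float, float] = (0.2, 40.0),
                baseline: tuple[float, float] = (-200.0, 0.0),
                channel_set=POSTERIOR_CHANNELS, order: int = 4,
                by: str = "condition") -> ERPResult:
    """Condition-mean ERP traces with a posterior-average summary.

    Band-pass filters (zero-phase Butterworth), baseline-corrects, averages
    across trials per condition, and additionally averages across
    ``channel_set`` for the summary traces.
    """
    post_idx = epochs.channel_indices(channel_set)
    filtered = EpochedEEG(_bandpass(epochs.data, epochs.sfreq, band, order),
                          epochs.times, epochs.sfreq, epochs.ch_names,
                          epochs.metadata, epochs.lock, epochs.seed)
    corrected = baseline_correct(filtered, baseline)
    traces = {}
    post = {}
    for cond, grp in corrected.metadata.groupby(by):
        idx = corrected.metadata.index.get_indexer(grp.index)
        mean_ct = corrected.data[idx].mean(axis=0)
        traces[str(cond)] = mean_ct
        post[str(cond)] = mean_ct[post_idx].mean(axis=0)
    frame = pd.DataFrame({"time_ms": epochs.times, **post})
    return ERPResult(times=epochs.times, traces=traces, posterior_traces=frame)


def ping_contrast(ping_epochs: list[EpochedEEG],
                  pseudo_epochs: list[EpochedEEG],
                  window_ms: tuple[float, float] = (200.0, 400.0),
                  n_randomizations: int = 100_000, alpha: float = 0.05,
                  band: tuple[float, float] = (0.2, 40.0),
                  baseline: tuple[float, float] = (-200.0, 0.0),
                  seed: int | None = None) -> ERPResult:
    """Per-channel ping vs pseudo-ping amplitude contrast.

    Both inputs are per-participant lists of ping-locked epochs. Per
    participant and channel, the trial-mean amplitude inside ``window_ms``
    is computed after filtering and baseline correction; the group statistic
    per channel is the mean paired difference. The null is built by randomly
    sign-flipping each participant's difference (participant-level
    exchangeability), and two-sided p-values are Bonferroni-corrected across
    channels.
    """
    if len(ping_epochs) != len(pseudo_epochs) or not ping_epochs:
        raise ValueError("need paired, non-empty participant lists")
    ch_names = ping_epochs[0].ch_names
    for ep in (*ping_epochs, *pseudo_epochs):
        if list(ep.ch_names) != list(ch_names):
            raise ValueError("all participants must share the same channel set")

    def _mean_amp(ep: EpochedEEG) -> np.ndarray:
        corrected = baseline_correct(
            EpochedEEG(_bandpass(ep.data, ep.sfreq, band), ep.times, ep.sfreq,
                       ep.ch_names, ep.metadata, ep.lock, ep.seed), baseline)
        mask = (ep.times >= window_ms[0]) & (ep.times <= window_ms[1])
        return corrected.data[:, :, mask].mean(axis=(0, 2))   # (C,)

    amp_ping = np.vstack([_mean_amp(e) for e in ping_epochs])      # (P, C)
    amp_pseudo = np.vstack([_mean_amp(e) for e in pseudo_epochs])
    diff = amp_ping - amp_pseudo
    n_p, n_c = diff.shape
    observed = diff.mean(axis=0)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_randomizations, n_p))
    null = signs @ diff / n_p                                      # (R, C)
    p_raw = (1.0 + (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)) \
        / (n_randomizations + 1.0)
    p_bonf = np.minimum(1.0, p_raw * n_c)
    contrast = pd.DataFrame({
        "channel": ch_names,
        "mean_diff_uv": observed,
        "p_raw": p_raw,
        "p_bonferroni": p_bonf,
        "significant": p_bonf <= alpha,
    })
    return ERPResult(contrast=contrast, n_randomizations=n_randomizations)
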