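"""Synthetic epoched EEG with ground-truth category signal.

The generative model mirrors the structure of a cued-recall ping experiment:

* background noise per trial and channel with a 1/f amplitude spectrum plus
  low-frequency oscillations (default a 10 Hz alpha rhythm) whose phase is
  drawn independently per trial;
* a category-specific multivariate pattern — a fixed channel-weight vector per
  top-level class — switched on under a half-sine temporal envelope whose
  onset latency jitters across trials (Normal(onset_mean, jitter_sd));
* on pinged trials, a biphasic visually-evoked response on posterior-weighted
  channels, peaking ~250 ms after the ping;
* a latency-regularization parameter rho in [0, 1]: on pinged trials the
  onset jitter SD shrinks by the factor (1 - rho), embodying the hypothesis
  that pings stabilise retrieval dynamics across trials. rho = 0 (the null,
  and the study's empirical conclusion) is the default.

All randomness flows from a single seed through independent named substreams
(patterns / noise / latencies / phases), so e.g. redrawing the noise never
perturbs the latencies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CHANNELS_10_20, POSTERIOR_CHANNELS, EpochedEEG

__all__ = ["SimulationConfig", "simulate_epochs"]

_STREAMS = {"patterns": 0, "noise": 1, "latencies": 2, "phases": 3}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EEG generator (times ms, amplitudes µV)."""

    n_participants: int = 29
    n_channels: int = 64
    sfreq: float = 250.0
    tmin_ms: float = -1000.0
    tmax_ms: float = 3000.0
    # background noise
    noise_sd_uv: float = 5.0
    noise_exponent: float = 1.0          # 1/f^exponent amplitude spectrum
    osc_amplitudes_uv: dict[float, float] = field(default_factory=lambda: {10.0: 2.0})
    # category signal (recall phase, latencies relative to cue onset)
    effect_amplitude_uv: float = 1.0
    onset_mean_ms: float = 900.0
    onset_jitter_sd_ms: float = 150.0
    response_duration_ms: float = 400.0
    # category signal during encoding (stimulus-locked perception)
    encoding_onset_mean_ms: float = 150.0
    encoding_onset_jitter_sd_ms: float = 30.0
    # ping-evoked response
    ping_amplitude_uv: float = 5.0
    ping_latency_ms: float = 250.0       # positive peak relative to ping onset
    ping_nonposterior_weight: float = 0.15  # kernel weight off the posterior set
    # latency regularization: jitter SD on ping trials scales by (1 - rho)
    regularization: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.sfreq <= 2 * 80:
            raise ValueError("sfreq must exceed twice the highest analysed band edge (80 Hz)")
        if not 0.0 <= self.regularization <= 1.0:
            raise ValueError("regularization rho must lie in [0, 1]")
        if self.tmax_ms <= self.tmin_ms:
            raise ValueError("tmax_ms must exceed tmin_ms")
        if not 1 <= self.n_channels <= len(CHANNELS_10_20):
            raise ValueError(f"n_channels must be in 1..{len(CHANNELS_10_20)}")

    @property
    def ch_names(self) -> list[str]:
        return list(CHANNELS_10_20[: self.n_channels])

    @property
    def times_ms(self) -> np.ndarray:
        n = int(round((self.tmax_ms - self.tmin_ms) * self.sfreq / 1000.0))
        return self.tmin_ms + np.arange(n) * (1000.0 / self.sfreq)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["osc_amplitudes_uv"] = {str(k): v for k, v in self.osc_amplitudes_uv.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "osc_amplitudes_uv" in d:
            d["osc_amplitudes_uv"] = {float(k): float(v)
                                      for k, v in d["osc_amplitudes_uv"].items()}
        return cls(**d)


def _stream(config_seed, name: str) -> np.random.Generator:
    entropy = 0 if config_seed is None else int(config_seed)
    return np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=(_STREAMS[name],)))


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...], n_times: int,
                      sfreq: float, exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with 1/f^exponent amplitude spectrum, unit-free SD ``sd``."""
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = rng.standard_normal(shape + (freqs.size,)) + 1j * rng.standard_normal(shape + (freqs.size,))
    noise = np.fft.irfft(spec * amp, n=n_times, axis=-1)
    std = noise.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return noise / std * sd


def _class_patterns(rng: np.random.Generator, classes: list[str], n_channels: int) -> dict[str, np.ndarray]:
    """Fixed unit-norm channel-weight vector per class, pairwise non-collinear."""
    patterns: dict[str, np.ndarray] = {}
    for cls in classes:
        for _ in range(100):
            v = rng.standard_normal(n_channels)
            v /= np.linalg.norm(v)
            if all(abs(v @ p) < 0.9 for p in patterns.values()):
                patterns[cls] = v
                break
        else:  # pragma: no cover - virtually impossible for n_channels >= 2
            raise RuntimeError("could not draw non-collinear class patterns")
    return patterns


def _ping_kernel(times_ms: np.ndarray, peak_ms: float, amplitude: float) -> np.ndarray:
    """Biphasic canonical evoked waveform: positive peak at ``peak_ms`` after
    the ping preceded by a smaller negative deflection."""
    pos = np.exp(-0.5 * ((times_ms - peak_ms) / 60.0) ** 2)
    neg = -0.5 * np.exp(-0.5 * ((times_ms - peak_ms + 130.0) / 40.0) ** 2)
    return amplitude * (pos + neg)


def _half_sine_envelope(times_ms: np.ndarray, onset_ms: float, duration_ms: float) -> np.ndarray:
    x = (times_ms - onset_ms) / duration_ms
    env = np.sin(np.pi * np.clip(x, 0.0, 1.0))
    env[(x < 0) | (x > 1)] = 0.0
    return env


def _posterior_weights(ch_names: list[str], nonposterior: float = 0.15) -> np.ndarray:
    w = np.full(len(ch_names), nonposterior)
    post = set(POSTERIOR_CHANNELS)
    for i, name in enumerate(ch_names):
        if name in post:
            w[i] = 1.0
    return w


def simulate_epochs(design: pd.DataFrame, config: SimulationConfig,
                    lock: str = "cue") -> EpochedEEG:
    """Simulate epoched EEG for one participant's trial table.

    Parameters
    ----------
    design : trial table from :func:`pingdecode.design.generate_design`
        (optionally with pseudo-ping times for ``lock='ping'``).
    config : SimulationConfig
    lock : {'cue', 'ping', 'encoding_image'}
        Event placed at t = 0. ``'cue'`` epochs all recall trials relative to
        the retrieval cue; ``'ping'`` epochs recall trials relative to the
        (pseudo-)ping and requires ping/pseudo-ping times on every included
        trial; ``'encoding_image'`` epochs encoding trials relative to image
        onset.

    Returns
    -------
    EpochedEEG with float32 data, the trial-table rows used, and the seed.
    """
    if lock not in ("cue", "ping", "encoding_image"):
        raise ValueError(f"unknown lock {lock!r}")

    if lock == "encoding_image":
        table = design[design["phase"] == "encoding"].reset_index(drop=True)
    else:
        table = design[design["phase"] == "recall"].reset_index(drop=True)
    if table.empty:
        raise ValueError(f"design has no rows for lock={lock!r}")

    times = config.times_ms
    n_times = times.size
    n_trials = len(table)
    ch_names = config.ch_names
    n_ch = len(ch_names)

    if lock == "ping":
        if "pseudo_ping_time_ms" in table.columns:
            event_ms = table["pseudo_ping_time_ms"].to_numpy(float)
        else:
            event_ms = table["ping_time_ms"].to_numpy(float)
        if np.isnan(event_ms).any():
            raise ValueError(
                "lock='ping' requires a (pseudo-)ping time on every recall trial; "
                "run make_pseudo_pings first or drop no-ping trials"
            )
    else:
        event_ms = np.zeros(n_trials)
    # cue onset in the epoch's timebase (t=0 is the lock event)
    cue_ms = -event_ms

    pat_rng = _stream(config.seed, "patterns")
    noise_rng = _stream(config.seed, "noise")
    lat_rng = _stream(config.seed, "latencies")
    phase_rng = _stream(config.seed, "phases")

    classes = sorted(table["label_top"].unique())
    patterns = _class_patterns(pat_rng, classes, n_ch)

    data = _one_over_f_noise(noise_rng, (n_trials, n_ch), n_times, config.sfreq,
                             config.noise_exponent, config.noise_sd_uv)

    # shared-across-channels oscillatory background, random phase per trial
    t_s = times / 1000.0
    for freq, amp in config.osc_amplitudes_uv.items():
        phases = phase_rng.uniform(0, 2 * np.pi, size=n_trials)
        osc = amp * np.sin(2 * np.pi * freq * t_s[None, :] + phases[:, None])
        data += osc[:, None, :]

    if lock == "encoding_image":
        onset_mean, onset_sd = config.encoding_onset_mean_ms, config.encoding_onset_jitter_sd_ms
        is_ping = np.zeros(n_trials, dtype=bool)
    else:
        onset_mean, onset_sd = config.onset_mean_ms, config.onset_jitter_sd_ms
        is_ping = (table["condition"] != "none").to_numpy()

    jitter_sd = onset_sd * np.where(is_ping, 1.0 - config.regularization, 1.0)
    onsets = onset_mean + lat_rng.standard_normal(n_trials) * jitter_sd

    post_w = _posterior_weights(ch_names, config.ping_nonposterior_weight)
    for i in range(n_trials):
        if config.effect_amplitude_uv != 0.0:
            env = _half_sine_envelope(times, cue_ms[i] + onsets[i],
                                      config.response_duration_ms)
            if env.any():
                pat = patterns[table.at[i, "label_top"]]
                data[i] += config.effect_amplitude_uv * pat[:, None] * env[None, :]
        if lock != "encoding_image" and is_ping[i] and config.ping_amplitude_uv != 0.0:
            ping_t0 = cue_ms[i] + table.at[i, "ping_time_ms"]
            # kernel defined relative to ping onset
            kern = _ping_kernel(times - ping_t0, config.ping_latency_ms,
                                config.ping_amplitude_uv)
            data[i] += post_w[:, None] * kern[None, :]

    return EpochedEEG(data.astype(np.float32), times, config.sfreq, ch_names,
                      table.copy(), lock, config.seed)
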