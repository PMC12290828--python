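"""Group-level inference for time-resolved decoding.

Two complementary tests are provided. The two-level Monte-Carlo permutation
test builds a group null window-by-window: each second-level draw samples one
first-level (label-shuffled, within-participant) decodability value per
participant and averages them; the empirical group mean is then ranked within
those permuted averages. The Wilcoxon signed-rank contrast compares two
paired per-participant series directly. Both adjust p-values across the
analysed windows for the false discovery rate with the Benjamini-Yekutieli
procedure, which remains valid when tests are dependent across time.

Permutation p-values use the add-one convention
p = (1 + #{null at least as extreme}) / (n + 1), which is strictly positive
and valid at any permutation count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon
from statsmodels.stats.multitest import multipletests

from .containers import EpochedEEG

__all__ = ["StatConfig", "StatResult", "two_level_permutation", "wilcoxon_contrast",
           "fdr_dependent", "trial_count_pvalue_simulation",
           "intertrial_variance_contrast", "ANALYSIS_WINDOWS_MS"]

#: statistical analysis windows per time-lock (ms)
ANALYSIS_WINDOWS_MS = {"ping": (0.0, 500.0), "cue": (500.0, 2000.0)}


@dataclass
class StatConfig:
    """Group-inference parameters."""

    n_second_level: int = 100_000
    alpha: float = 0.05
    analysis_window_ms: tuple[float, float] | None = None
    sided: str = "greater"        # empirical vs null direction for decodability
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_second_level < 1:
            raise ValueError("n_second_level must be >= 1")
        if self.sided not in ("greater", "less", "two-sided"):
            raise ValueError(f"unknown sidedness {self.sided!r}")


@dataclass
class StatResult:
    """Per-window test outcome."""

    window_times: np.ndarray = field(repr=False)
    p_raw: np.ndarray = field(repr=False)
    p_fdr: np.ndarray = field(repr=False)
    significant: np.ndarray = field(repr=False)
    test: str = ""
    n_second_level: int | None = None
    statistic: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_time_ms": self.window_times,
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "significant": self.significant,
        })


def _restrict(window_times, cfg: StatConfig):
    window_times = np.asarray(window_times, dtype=float)
    if cfg.analysis_window_ms is None:
        return window_times, np.ones(window_times.size, dtype=bool)
    lo, hi = cfg.analysis_window_ms
    mask = (window_times >= lo) & (window_times <= hi)
    if not mask.any():
        raise ValueError(f"analysis window [{lo}, {hi}] ms contains no windows")
    return window_times[mask], mask


def fdr_dependent(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment (valid under dependence).

    Applies the harmonic-number correction c(m) = sum_{i<=m} 1/i to the
    Benjamini-Hochberg step-up, enforces monotonicity, and clips at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def two_level_permutation(empirical: np.ndarray, first_level: np.ndarray,
                          cfg: StatConfig = StatConfig(),
                          window_times: np.ndarray | None = None) -> StatResult:
    """Two-level Monte-Carlo permutation test of group decodability.

    Parameters
    ----------
    empirical : (n_participants, n_windows)
        Per-participant empirical metric per window.
    first_level : (n_participants, n_permutations, n_windows)
        Per-participant label-shuffle distribution.
    cfg : StatConfig
        ``cfg.sided='greater'`` tests empirical group mean > permuted means.
    window_times : optional, for the analysis-window restriction and output.

    Per window, each of ``cfg.n_second_level`` draws samples (with
    replacement) one first-level value per participant and averages them;
    p = (1 + #{null >= observed}) / (n + 1) for the right-sided test. The
    restriction to the analysis window is applied before FDR correction, so
    the correction spans only the tested windows.
    """
    empirical = np.asarray(empirical, dtype=float)
    first_level = np.asarray(first_level, dtype=float)
    if empirical.ndim != 2 or first_level.ndim != 3:
        raise ValueError("empirical must be (P, W); first_level (P, K, W)")
    n_p, n_w = empirical.shape
    if first_level.shape[0] != n_p or first_level.shape[2] != n_w:
        raise ValueError("empirical and first_level shapes disagree")
    if first_level.shape[1] < 1:
        raise ValueError("need at least one first-level permutation per participant")
    if window_times is None:
        window_times = np.arange(n_w, dtype=float)
    times, mask = _restrict(window_times, cfg)
    widx = np.flatnonzero(mask)

    rng = np.random.default_rng(cfg.seed)
    n2 = cfg.n_second_level
    k = first_level.shape[1]
    obs = empirical.mean(axis=0)
    p_raw = np.empty(widx.size)
    rows = np.arange(n_p)
    for j, w in enumerate(widx):
        idx = rng.integers(0, k, size=(n2, n_p))
        null = first_level[rows[None, :], idx, w].mean(axis=1)
        if cfg.sided == "greater":
            extreme = np.count_nonzero(null >= obs[w])
        elif cfg.sided == "less":
            extreme = np.count_nonzero(null <= obs[w])
        else:
            extreme = 2 * min(np.count_nonzero(null >= obs[w]),
                              np.count_nonzero(null <= obs[w]))
        p_raw[j] = min(1.0, (1.0 + extreme) / (n2 + 1.0))
    p_fdr = fdr_dependent(p_raw)
    return StatResult(times, p_raw, p_fdr, p_fdr <= cfg.alpha,
                      test="two_level_permutation", n_second_level=n2,
                      statistic=obs[widx])


def wilcoxon_contrast(a: np.ndarray, b: np.ndarray,
                      cfg: StatConfig = StatConfig(),
                      window_times: np.ndarray | None = None) -> StatResult:
    """Paired Wilcoxon signed-rank contrast per window, FDR-corrected.

    ``a`` and ``b`` are (n_participants, n_windows) paired arrays. The test
    is exact for n <= 25 (no ties/zeros), otherwise the normal approximation
    with continuity correction is used. All-zero differences give p = 1 with
    a warning. Sidedness follows ``cfg.sided`` (alternative: a vs b).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal shapes")
    n_p, n_w = a.shape
    if n_p < 5:
        raise ValueError("Wilcoxon contrast needs at least 5 participants")
    if window_times is None:
        window_times = np.arange(n_w, dtype=float)
    times, mask = _restrict(window_times, cfg)
    widx = np.flatnonzero(mask)
    p_raw = np.empty(widx.size)
    stat = np.empty(widx.size)
    for j, w in enumerate(widx):
        d = a[:, w] - b[:, w]
        if np.all(d == 0):
            warnings.warn(f"window {window_times[w]} ms: all paired differences "
                          "are zero; p set to 1", stacklevel=2)
            p_raw[j], stat[j] = 1.0, 0.0
            continue
        exact_ok = n_p <= 25 and not np.any(d == 0) and np.unique(np.abs(d)).size == n_p
        method = "exact" if exact_ok else "approx"
        res = _scipy_wilcoxon(a[:, w], b[:, w], alternative=cfg.sided,
                              correction=(method == "approx"), method=method)
        p_raw[j], stat[j] = float(res.pvalue), float(res.statistic)
    p_fdr = fdr_dependent(p_raw)
    return StatResult(times, p_raw, p_fdr, p_fdr <= cfg.alpha,
                      test="wilcoxon_signed_rank", statistic=stat)


# ---------------------------------------------------------------------------
# supplementary simulations


def trial_count_pvalue_simulation(effect: str = "present",
                                  trial_grid=(40, 120, 240),
                                  class_grid=(2,),
                                  n_participants: int = 10,
                                  n_channels: int = 16,
                                  n_windows: int = 6,
                                  n_signal_windows: int = 3,
                                  effect_size: float = 0.8,
                                  n_second_level: int = 2000,
                                  n_label_shuffles: int = 20,
                                  n_replicates: int = 1,
                                  seed: int | None = None) -> pd.DataFrame:
    """How trial count (and class count) shapes two-level p-values.

    For each grid cell, feature-level data are simulated per participant
    (Gaussian noise; when ``effect='present'``, class-mean separation of
    ``effect_size`` SD in the last ``n_signal_windows`` windows), decoded
    with the standard LDA path, and passed through the two-level permutation
    test. Reported per cell: the median p across the signal windows and the
    SEM (SD) of the second-level null distribution, whose shrinkage with
    trial count is the phenomenon of interest — more trials tighten the
    shuffle null and so reduce p-values, but only when an effect exists.
    """
    from .containers import FeatureSeries
    from .decoding import DecoderConfig, decode_timecourse, shuffled_decode

    if effect not in ("present", "absent"):
        raise ValueError("effect must be 'present' or 'absent'")
    if not len(trial_grid) or not len(class_grid):
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for n_classes in class_grid:
        for n_trials in trial_grid:
            sig_ps, all_ps, rep_sems = [], [], []
            for _rep in range(n_replicates):
                emp, shuf, null_sds = [], [], []
                for _p in range(n_participants):
                    labels = np.repeat(np.arange(n_classes),
                                       int(np.ceil(n_trials / n_classes)))[:n_trials]
                    X = rng.standard_normal((n_trials, n_channels, n_windows))
                    if effect == "present":
                        patterns = rng.standard_normal((n_classes, n_channels))
                        patterns /= np.linalg.norm(patterns, axis=1, keepdims=True)
                        for w in range(n_windows - n_signal_windows, n_windows):
                            X[:, :, w] += effect_size * patterns[labels]
                    fs = FeatureSeries(X, np.arange(n_windows, dtype=float) * 20.0,
                                       [f"ch{i}" for i in range(n_channels)])
                    dcfg = DecoderConfig(n_folds=5, n_repetitions=1,
                                         metric="auc" if n_classes == 2 else "accuracy",
                                         n_label_shuffles=n_label_shuffles,
                                         shuffle_repetitions=1,
                                         seed=int(rng.integers(2 ** 31)))
                    emp.append(decode_timecourse(fs, labels, dcfg).empirical)
                    s = shuffled_decode(fs, labels, dcfg)
                    shuf.append(s)
                    null_sds.append(s.std(axis=0, ddof=1).mean())
                empirical = np.vstack(emp)
                first_level = np.stack(shuf)
                scfg = StatConfig(n_second_level=n_second_level,
                                  seed=int(rng.integers(2 ** 31)))
                res = two_level_permutation(empirical, first_level, scfg)
                sig_slice = slice(n_windows - n_signal_windows, n_windows)
                sig_ps.extend(res.p_raw[sig_slice].tolist())
                all_ps.extend(res.p_raw.tolist())
                rep_sems.append(float(np.mean(null_sds)))
            rows.append({
                "n_trials": n_trials,
                "n_classes": n_classes,
                "effect": effect,
                "median_p": float(np.median(sig_ps)),
                "median_p_all": float(np.median(all_ps)),
                "shuffled_sem": float(np.mean(rep_sems)),
            })
    return pd.DataFrame(rows)


def intertrial_variance_contrast(ping_epochs: list[EpochedEEG],
                                 noping_epochs: list[EpochedEEG],
                                 window_ms: tuple[float, float] = (500.0, 2000.0),
                                 cfg: StatConfig | None = None) -> pd.DataFrame:
    """Does pinging reduce across-trial variance of raw activity?

    Per participant and condition, the across-trial variance is computed per
    channel and time sample and averaged over ``window_ms``; the per-channel
    ping vs no-ping difference is then tested with a paired Wilcoxon across
    participants (default two-sided).

    Returns a DataFrame with one row per channel: mean variance per
    condition, the paired statistic, raw and BY-adjusted p.
    """
    if cfg is None:
        cfg = StatConfig(sided="two-sided")
    if len(ping_epochs) != len(noping_epochs) or not ping_epochs:
        raise ValueError("need paired, non-empty participant lists")
    ch_names = ping_epochs[0].ch_names

    def _cond_var(ep: EpochedEEG) -> np.ndarray:
        if ep.n_trials < 2:
            raise ValueError("across-trial variance needs >= 2 trials per condition")
        mask = (ep.times >= window_ms[0]) & (ep.times <= window_ms[1])
        if not mask.any():
            raise ValueError(f"window {window_ms} ms lies outside the epoch")
        return ep.data[:, :, mask].astype(float).var(axis=0, ddof=1).mean(axis=1)

    vp = np.vstack([_cond_var(e) for e in ping_epochs])     # (P, C)
    vn = np.vstack([_cond_var(e) for e in noping_epochs])
    res = wilcoxon_contrast(vp, vn, cfg)
    return pd.DataFrame({
        "channel": ch_names,
        "var_ping": vp.mean(axis=0),
        "var_noping": vn.mean(axis=0),
        "statistic": res.statistic,
        "p_raw": res.p_raw,
        "p_fdr": res.p_fdr,
    })
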