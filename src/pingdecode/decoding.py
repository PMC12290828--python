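"""Time-resolved linear-discriminant decoding.

Per time window, a linear discriminant analysis (LDA) with automatic
Ledoit-Wolf shrinkage of the pooled within-class covariance is trained and
evaluated under repeated stratified k-fold cross-validation. Binary problems
are scored with the rank-based AUC (the Mann-Whitney statistic normalised by
n0*n1, equivalent to the area under the ROC curve); multiclass problems with
accuracy, with chance = 1/n_classes recorded alongside.

The LDA is solved in closed form (shrunk covariance solve against class-mean
differences), which matches scikit-learn's ``LinearDiscriminantAnalysis``
with ``solver='lsqr', shrinkage='auto'`` up to numerical precision while
being fast enough for the permutation-heavy pipeline; the equivalence is
exercised in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .containers import DecodingTimecourse, FeatureSeries

__all__ = ["DecoderConfig", "decode_timecourse", "shuffled_decode", "cross_decode",
           "level_selection", "rank_auc"]


@dataclass
class DecoderConfig:
    """Cross-validation and permutation parameters."""

    n_folds: int = 5
    n_repetitions: int = 25
    metric: str = "auc"                  # 'auc' (binary) or 'accuracy'
    n_label_shuffles: int = 100
    shuffle_repetitions: int = 3
    # combine folds by unweighted fold average (default) or by pooling
    # predictions across folds before scoring (differs when folds are uneven)
    fold_aggregation: str = "fold_average"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.metric not in ("auc", "accuracy"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.fold_aggregation not in ("fold_average", "pooled"):
            raise ValueError(f"unknown fold_aggregation {self.fold_aggregation!r}")
        if self.fold_aggregation == "pooled" and self.metric != "accuracy":
            raise ValueError("pooled fold aggregation is defined for accuracy only")


# ---------------------------------------------------------------------------
# closed-form shrinkage LDA


def ledoit_wolf_shrinkage(Xc: np.ndarray) -> float:
    """Ledoit-Wolf optimal shrinkage intensity for centred data ``Xc``."""
    n, p = Xc.shape
    if p == 1:
        return 0.0
    X2 = Xc ** 2
    emp_cov_trace = X2.sum(axis=0) / n
    mu = emp_cov_trace.sum() / p
    beta_ = np.sum(X2.T @ X2)
    delta_ = np.sum((Xc.T @ Xc) ** 2) / n ** 2
    beta = 1.0 / (p * n) * (beta_ / n - delta_)
    delta = (delta_ - 2.0 * mu * emp_cov_trace.sum() + p * mu ** 2) / p
    if delta == 0:
        return 0.0
    beta = min(beta, delta)
    return float(beta / delta)


def _class_stats(X: np.ndarray, y: np.ndarray, classes: np.ndarray):
    """Per-class means and the shrinkage-averaged within-class covariance."""
    n, p = X.shape
    means = np.empty((classes.size, p))
    cov = np.zeros((p, p))
    for k, cls in enumerate(classes):
        Xk = X[y == cls]
        means[k] = Xk.mean(axis=0)
        Xc = Xk - means[k]
        # shrink on standardised features so the intensity is scale-invariant,
        # rescaling the shrunk matrix back afterwards
        scale = Xc.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = Xc / scale
        shrink = ledoit_wolf_shrinkage(Xs)
        Ss = Xs.T @ Xs / len(Xk)
        mu = np.trace(Ss) / p
        Ss = (1.0 - shrink) * Ss + shrink * mu * np.eye(p)
        cov += (len(Xk) / n) * (scale[:, None] * Ss * scale[None, :])
    if not np.any(cov):
        warnings.warn("constant features: covariance is zero, using identity",
                      stacklevel=3)
        cov = np.eye(p)
    return means, cov


def _lda_scores(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                classes: np.ndarray) -> np.ndarray:
    """Class discriminant scores for test data, shape (n_test, n_classes)."""
    n = len(ytr)
    means, cov = _class_stats(Xtr, ytr, classes)
    try:
        coefs = np.linalg.solve(cov, means.T)          # (p, K)
    except np.linalg.LinAlgError:
        coefs = np.linalg.lstsq(cov, means.T, rcond=None)[0]
    priors = np.array([(ytr == c).sum() / n for c in classes])
    intercept = -0.5 * np.einsum("kp,pk->k", means, coefs) + np.log(priors)
    return Xte @ coefs + intercept


def rank_auc(scores: np.ndarray, y01: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) statistic with midranks for ties."""
    n1 = int(y01.sum())
    n0 = y01.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[y01 == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def _fold_metric(Xtr, ytr, Xte, yte, classes, metric: str) -> float:
    scores = _lda_scores(Xtr, ytr, Xte, classes)
    if metric == "auc":
        return rank_auc(scores[:, 1] - scores[:, 0], (yte == classes[1]).astype(int))
    pred = classes[np.argmax(scores, axis=1)]
    return float(np.mean(pred == yte))


def _windows_metric(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                    yte: np.ndarray, classes: np.ndarray, metric: str) -> np.ndarray:
    """Fit the shrinkage LDA independently per window, batched over windows.

    ``Xtr``/``Xte`` are (n, p, W) slices; the result equals calling
    :func:`_fold_metric` window by window (tested), with the per-window
    Ledoit-Wolf solve vectorised across the window axis.
    """
    n, p, n_w = Xtr.shape
    n_k = classes.size
    eye = np.eye(p)
    means = np.empty((n_k, p, n_w))
    cov = np.zeros((n_w, p, p))
    priors = np.empty(n_k)
    for k, cls in enumerate(classes):
        Xk = Xtr[ytr == cls]
        nk = len(Xk)
        priors[k] = nk / n
        means[k] = Xk.mean(axis=0)
        Xc = Xk - means[k][None]
        scale = np.sqrt(np.einsum("npw,npw->pw", Xc, Xc) / nk)
        scale[scale == 0] = 1.0
        Xs = Xc / scale[None]
        Ss = np.einsum("npw,nqw->wpq", Xs, Xs) / nk
        X2 = Xs ** 2
        trace_sum = np.einsum("npw->w", X2) / nk
        mu = trace_sum / p
        rowsum = X2.sum(axis=1)                      # (n, W)
        beta_ = np.einsum("nw,nw->w", rowsum, rowsum)
        delta_ = np.einsum("wpq,wpq->w", Ss, Ss)
        beta = (beta_ / nk - delta_) / (p * nk)
        delta = (delta_ - 2.0 * mu * trace_sum + p * mu ** 2) / p
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(delta > 0, np.minimum(beta, delta) / np.where(delta > 0, delta, 1.0), 0.0)
        shrunk = (1.0 - shrink)[:, None, None] * Ss \
            + (shrink * mu)[:, None, None] * eye[None]
        cov += priors[k] * np.einsum("wpq,pw,qw->wpq", shrunk, scale, scale)
    # degenerate (all-constant) windows: fall back to the identity metric
    dead = np.abs(cov).sum(axis=(1, 2)) == 0
    if dead.any():
        warnings.warn("constant features: covariance is zero, using identity",
                      stacklevel=3)
        cov[dead] = eye
    try:
        coefs = np.linalg.solve(cov, means.transpose(2, 1, 0))   # (W, p, K)
    except np.linalg.LinAlgError:
        coefs = np.stack([np.linalg.lstsq(cov[w], means[:, :, w].T, rcond=None)[0]
                          for w in range(n_w)])
    intercept = -0.5 * np.einsum("kpw,wpk->wk", means, coefs) + np.log(priors)[None]
    scores = np.einsum("npw,wpk->nwk", Xte, coefs) + intercept[None]
    if metric == "auc":
        d = scores[:, :, 1] - scores[:, :, 0]                    # (n_te, W)
        ranks = rankdata(d, axis=0)
        pos = yte == classes[1]
        n1 = int(pos.sum())
        n0 = yte.size - n1
        return (ranks[pos].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    pred = classes[np.argmax(scores, axis=2)]                    # (n_te, W)
    return (pred == yte[:, None]).mean(axis=0)


# ---------------------------------------------------------------------------
# public operations


def _validate(fs: FeatureSeries, labels: np.ndarray, cfg: DecoderConfig):
    labels = np.asarray(labels)
    if labels.shape[0] != fs.n_trials:
        raise ValueError("labels do not match the trial axis")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < cfg.n_folds:
        lacking = classes[counts.argmin()]
        raise ValueError(
            f"class {lacking!r} has {counts.min()} trials, fewer than "
            f"n_folds={cfg.n_folds}"
        )
    metric = cfg.metric
    if metric == "auc" and classes.size != 2:
        raise ValueError("AUC is defined for binary problems only")
    return labels, classes


def _cv_timecourse(values: np.ndarray, labels: np.ndarray, classes: np.ndarray,
                   n_folds: int, n_reps: int, metric: str,
                   rng: np.random.Generator,
                   fold_aggregation: str = "fold_average") -> np.ndarray:
    """Metric per window over folds x repetitions.

    'fold_average' takes the unweighted mean of per-fold metrics; 'pooled'
    (accuracy only) pools predictions across a repetition's folds, i.e.
    weights folds by their size.
    """
    n_windows = values.shape[2]
    acc = np.zeros(n_windows)
    norm = 0.0
    for _ in range(n_reps):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for tr, te in skf.split(values[:, :, 0], labels):
            fold = _windows_metric(values[tr], labels[tr], values[te],
                                   labels[te], classes, metric)
            if fold_aggregation == "pooled":
                acc += fold * te.size
                norm += te.size
            else:
                acc += fold
                norm += 1.0
    return acc / norm


def decode_timecourse(fs: FeatureSeries, labels, cfg: DecoderConfig = DecoderConfig()
                      ) -> DecodingTimecourse:
    """Repeated stratified k-fold LDA decoding, one metric value per window."""
    labels, classes = _validate(fs, np.asarray(labels), cfg)
    rng = np.random.default_rng(cfg.seed)
    emp = _cv_timecourse(fs.values, labels, classes, cfg.n_folds,
                         cfg.n_repetitions, cfg.metric, rng,
                         cfg.fold_aggregation)
    chance = 0.5 if cfg.metric == "auc" else 1.0 / classes.size
    return DecodingTimecourse(fs.window_times, emp, None, cfg.metric, chance,
                              classes.size)


def shuffled_decode(fs: FeatureSeries, labels, cfg: DecoderConfig = DecoderConfig()
                    ) -> np.ndarray:
    """First-level label-shuffle null: decode ``n_label_shuffles`` random
    label permutations, each with ``shuffle_repetitions`` CV repetitions.

    Returns an array of shape (n_label_shuffles, n_windows).
    """
    labels, classes = _validate(fs, np.asarray(labels), cfg)
    rng = np.random.default_rng(cfg.seed)
    out = np.empty((cfg.n_label_shuffles, fs.n_windows))
    for s in range(cfg.n_label_shuffles):
        perm = rng.permutation(fs.n_trials)
        out[s] = _cv_timecourse(fs.values, labels[perm], classes, cfg.n_folds,
                                cfg.shuffle_repetitions, cfg.metric, rng,
                                cfg.fold_aggregation)
    return out


def cross_decode(train_fs: FeatureSeries, train_labels, test_fs: FeatureSeries,
                 test_labels, cfg: DecoderConfig = DecoderConfig(),
                 train_window: tuple[float, float] = (100.0, 1000.0),
                 pool: str = "instances") -> DecodingTimecourse:
    """Train one LDA on a training-phase window, test on every test window.

    Training instances are, per the ``pool`` mode, either every (trial,
    window) sample with window centre inside ``train_window`` pooled as an
    independent instance ('instances', default — preserves temporal
    variance), or the per-trial average over those windows ('average'). No
    cross-validation is applied: train and test phases are disjoint.
    """
    if train_fs.n_features != test_fs.n_features:
        raise ValueError("train and test feature spaces differ")
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    mask = train_fs.window_mask(*train_window)
    if not mask.any():
        raise ValueError(f"no training windows inside {train_window} ms")
    classes = np.unique(train_labels)
    if cfg.metric == "auc" and classes.size != 2:
        raise ValueError("AUC is defined for binary problems only")
    sub = train_fs.values[:, :, mask]
    if pool == "instances":
        Xtr = np.moveaxis(sub, 2, 1).reshape(-1, train_fs.n_features)
        ytr = np.repeat(train_labels, mask.sum())
    elif pool == "average":
        Xtr = sub.mean(axis=2)
        ytr = train_labels
    else:
        raise ValueError(f"unknown pool mode {pool!r}")
    emp = np.empty(test_fs.n_windows)
    for w in range(test_fs.n_windows):
        emp[w] = _fold_metric(Xtr, ytr, test_fs.values[:, :, w], test_labels,
                              classes, cfg.metric)
    chance = 0.5 if cfg.metric == "auc" else 1.0 / classes.size
    return DecodingTimecourse(test_fs.window_times, emp, None, cfg.metric,
                              chance, classes.size)


def level_selection(participants: list[tuple[FeatureSeries, "object"]],
                    cfg: DecoderConfig = DecoderConfig(metric="accuracy"),
                    stat_cfg=None, levels=("top", "mid", "bot")):
    """Choose the most robustly decodable category level on no-ping trials.

    Parameters
    ----------
    participants : list of (FeatureSeries, labels_frame)
        One entry per participant; ``labels_frame`` is a DataFrame holding a
        label column per level (``label_top`` / ``label_mid`` / ``label_bot``).
    cfg : DecoderConfig (accuracy metric; chance differs per level)
    stat_cfg : stats.StatConfig or None

    Per level, each participant is decoded (empirical + first-level shuffles),
    then a Wilcoxon signed-rank test compares empirical against the
    shuffle-mean per window, FDR-corrected (Benjamini-Yekutieli).

    Selection rule: the level with the most FDR-significant windows; ties —
    including the all-zero tie — go to the level with the fewest classes,
    i.e. the most trials per class (the conservative default).

    Returns (selected_level, {level: group DecodingTimecourse},
    {level: StatResult}).
    """
    from .stats import StatConfig, wilcoxon_contrast

    if stat_cfg is None:
        stat_cfg = StatConfig()
    if cfg.metric != "accuracy":
        raise ValueError("level selection compares levels on accuracy")
    results: dict[str, DecodingTimecourse] = {}
    stats_out = {}
    n_sig = {}
    n_classes_per_level = {}
    for level in levels:
        col = f"label_{level}"
        emp_rows, shuf_rows = [], []
        window_times = None
        n_classes = None
        for fs, frame in participants:
            if col not in frame:
                raise ValueError(f"labels for level {level!r} missing")
            labels = np.asarray(frame[col])
            tc = decode_timecourse(fs, labels, cfg)
            shuf = shuffled_decode(fs, labels, cfg)
            emp_rows.append(tc.empirical)
            shuf_rows.append(shuf)
            window_times = tc.window_times
            n_classes = tc.n_classes
        empirical = np.vstack(emp_rows)
        shuffled = np.stack(shuf_rows)
        results[level] = DecodingTimecourse(window_times, empirical, shuffled,
                                            "accuracy", 1.0 / n_classes, n_classes)
        res = wilcoxon_contrast(empirical, shuffled.mean(axis=1), stat_cfg,
                                window_times=window_times)
        stats_out[level] = res
        n_sig[level] = int(res.significant.sum())
        n_classes_per_level[level] = n_classes
    selected = min(levels, key=lambda lv: (-n_sig[lv], n_classes_per_level[lv]))
    return selected, results, stats_out
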