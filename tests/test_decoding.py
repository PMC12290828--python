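"""Time-resolved LDA decoding against sklearn and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import ledoit_wolf_shrinkage as sk_lw
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from pingdecode.decoding import (DecoderConfig, _lda_scores, cross_decode,
                                 decode_timecourse, ledoit_wolf_shrinkage,
                                 level_selection, rank_auc, shuffled_decode)
from pingdecode.stats import StatConfig

from conftest import class_pattern_features, make_features


class TestLDAEquivalence:
    """The closed-form shrinkage LDA must reproduce sklearn's
    lsqr/auto-shrinkage solver; sklearn is the oracle, not the implementation."""

    @pytest.mark.parametrize("n,p", [(40, 8), (30, 15), (100, 3)])
    def test_ledoit_wolf_shrinkage_matches_sklearn(self, n, p):
        rng = np.random.default_rng(n + p)
        Xc = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
        Xc -= Xc.mean(axis=0)
        assert np.isclose(ledoit_wolf_shrinkage(Xc),
                          sk_lw(Xc, assume_centered=True), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_binary_decision_function_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 10)) @ rng.standard_normal((10, 10))
        y = rng.integers(0, 2, 60)
        X[y == 1] += 0.4
        Xte = rng.standard_normal((30, 10))
        s = _lda_scores(X, y, Xte, np.array([0, 1]))
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(X, y)
        assert np.allclose(s[:, 1] - s[:, 0], clf.decision_function(Xte), atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_multiclass_predictions_match_sklearn(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.standard_normal((90, 6)) * np.array([1, 5, 0.2, 1, 3, 1])
        y = rng.integers(0, 3, 90)
        X[y == 2] += 0.8
        Xte = rng.standard_normal((40, 6))
        s = _lda_scores(X, y, Xte, np.array([0, 1, 2]))
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(X, y)
        assert (np.argmax(s, axis=1) == clf.predict(Xte)).all()


class TestBatchedWindows:
    @pytest.mark.parametrize("metric,n_classes", [("auc", 2), ("accuracy", 3)])
    def test_batched_equals_per_window_fit(self, metric, n_classes):
        from pingdecode.decoding import _fold_metric, _windows_metric
        rng = np.random.default_rng(42)
        classes = np.arange(n_classes)
        ytr = rng.integers(0, n_classes, 48)
        yte = rng.integers(0, n_classes, 21)
        Xtr = rng.standard_normal((48, 7, 5)) * rng.uniform(0.2, 3.0, (1, 7, 1))
        Xte = rng.standard_normal((21, 7, 5))
        batched = _windows_metric(Xtr, ytr, Xte, yte, classes, metric)
        scalar = [_fold_metric(Xtr[:, :, w], ytr, Xte[:, :, w], yte, classes, metric)
                  for w in range(5)]
        assert np.allclose(batched, scalar, atol=1e-10)


class TestRankAUC:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_roc_integral_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        scores = rng.integers(0, 5, n).astype(float)   # force ties
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        assert np.isclose(rank_auc(scores, y), roc_auc_score(y, scores), atol=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            rank_auc(np.arange(4.0), np.ones(4, dtype=int))


class TestDecodeTimecourse:
    def test_chance_on_label_independent_features(self):
        rng = np.random.default_rng(8)
        fs = make_features(rng.standard_normal((60, 8, 12)))
        labels = np.repeat([0, 1], 30)
        tc = decode_timecourse(fs, labels, DecoderConfig(n_repetitions=3, seed=0))
        se = tc.empirical.std(ddof=1) / np.sqrt(tc.empirical.size)
        assert abs(tc.empirical.mean() - 0.5) < 3 * max(se, 0.01)

    def test_separable_patterns_decode_high(self):
        rng = np.random.default_rng(9)
        fs, labels = class_pattern_features(rng, effect=3.0)
        tc = decode_timecourse(fs, labels, DecoderConfig(n_repetitions=2, seed=0))
        assert tc.empirical[[6, 7, 8]].min() > 0.95
        assert tc.empirical[:5].mean() < 0.65

    def test_too_few_trials_per_class_errors(self):
        fs = make_features(np.random.default_rng(0).normal(size=(4, 3, 2)))
        labels = [0, 0, 1, 1]
        with pytest.raises(ValueError, match="fewer"):
            decode_timecourse(fs, labels, DecoderConfig(n_folds=5))

    def test_auc_multiclass_rejected(self):
        fs = make_features(np.random.default_rng(0).normal(size=(30, 3, 2)))
        labels = np.repeat([0, 1, 2], 10)
        with pytest.raises(ValueError, match="binary"):
            decode_timecourse(fs, labels, DecoderConfig(metric="auc"))

    def test_trial_order_invariance_after_canonical_sort(self):
        """Decoding depends on the trial set, not presentation order: sorting
        both orderings to a canonical key before seeding gives identical
        results."""
        rng = np.random.default_rng(10)
        fs, labels = class_pattern_features(rng, n_trials=40, n_windows=4,
                                            signal_windows=(2, 3))
        perm = rng.permutation(40)

        def canonical(values, labels):
            order = np.argsort(values[:, 0, 0], kind="stable")
            return make_features(values[order]), labels[order]

        fa, la = canonical(fs.values, labels)
        fb, lb = canonical(fs.values[perm], labels[perm])
        a = decode_timecourse(fa, la, DecoderConfig(n_repetitions=2, seed=5))
        b = decode_timecourse(fb, lb, DecoderConfig(n_repetitions=2, seed=5))
        assert np.array_equal(a.empirical, b.empirical)

    def test_pooled_accuracy_weights_folds_by_size(self):
        """Pooled predictions equal the fold-size-weighted accuracy; with 3
        folds over 40 trials fold sizes differ (14/13/13), so the two
        conventions disagree in general but agree on perfectly decodable
        data."""
        rng = np.random.default_rng(30)
        fs, labels = class_pattern_features(rng, n_trials=40, n_windows=3,
                                            signal_windows=(0, 1, 2), effect=50.0)
        base = DecoderConfig(metric="accuracy", n_folds=3, n_repetitions=1, seed=1)
        pooled = DecoderConfig(metric="accuracy", n_folds=3, n_repetitions=1,
                               fold_aggregation="pooled", seed=1)
        a = decode_timecourse(fs, labels, base)
        b = decode_timecourse(fs, labels, pooled)
        assert np.allclose(a.empirical, 1.0) and np.allclose(b.empirical, 1.0)
        with pytest.raises(ValueError, match="accuracy only"):
            DecoderConfig(metric="auc", fold_aggregation="pooled")

    def test_multiclass_chance_recorded(self):
        rng = np.random.default_rng(11)
        fs = make_features(rng.standard_normal((40, 4, 3)))
        labels = np.repeat([0, 1, 2, 3], 10)
        tc = decode_timecourse(fs, labels,
                               DecoderConfig(metric="accuracy", n_repetitions=1, seed=0))
        assert tc.chance == 0.25 and tc.n_classes == 4


class TestShuffledDecode:
    def test_shuffles_destroy_association(self):
        rng = np.random.default_rng(12)
        fs, labels = class_pattern_features(rng, n_trials=60, n_windows=5,
                                            signal_windows=(2, 3), effect=3.0)
        cfg = DecoderConfig(n_label_shuffles=100, shuffle_repetitions=1, seed=0)
        shuf = shuffled_decode(fs, labels, cfg)
        assert shuf.shape == (100, 5)
        assert abs(shuf.mean() - 0.5) < 0.02

    def test_seeded_reproducibility_and_single_row(self):
        rng = np.random.default_rng(13)
        fs, labels = class_pattern_features(rng, n_trials=30, n_windows=3)
        cfg = DecoderConfig(n_label_shuffles=1, shuffle_repetitions=1, seed=7)
        a = shuffled_decode(fs, labels, cfg)
        b = shuffled_decode(fs, labels, cfg)
        assert a.shape == (1, 3)
        assert np.array_equal(a, b)


class TestCrossDecode:
    def test_training_set_optimism(self):
        rng = np.random.default_rng(14)
        fs, labels = class_pattern_features(rng, n_trials=60, n_windows=10,
                                            signal_windows=tuple(range(10)),
                                            effect=1.0)
        cv = decode_timecourse(fs, labels, DecoderConfig(n_repetitions=2, seed=0))
        train_window = (fs.window_times[0], fs.window_times[-1])
        sanity = cross_decode(fs, labels, fs, labels,
                              DecoderConfig(seed=0), train_window=train_window)
        assert sanity.empirical.mean() >= cv.empirical.mean()

    def test_permuted_test_labels_give_chance(self):
        rng = np.random.default_rng(15)
        fs, labels = class_pattern_features(rng, n_trials=80, n_windows=10,
                                            signal_windows=tuple(range(10)),
                                            effect=2.0)
        perm = rng.permutation(labels)
        tc = cross_decode(fs, labels, fs, perm, DecoderConfig(seed=0),
                          train_window=(0.0, 180.0))
        assert abs(tc.empirical.mean() - 0.5) < 0.1

    def test_empty_training_window_errors(self):
        rng = np.random.default_rng(16)
        fs, labels = class_pattern_features(rng, n_trials=20, n_windows=4)
        with pytest.raises(ValueError, match="training window"):
            cross_decode(fs, labels, fs, labels, train_window=(9000.0, 9999.0))

    def test_test_window_span_honoured(self):
        rng = np.random.default_rng(17)
        fs, labels = class_pattern_features(rng, n_trials=40, n_windows=8)
        tc = cross_decode(fs, labels, fs, labels, train_window=(0.0, 60.0))
        assert np.array_equal(tc.window_times, fs.window_times)


class TestLevelSelection:
    def _participants(self, rng, signal_level="top", n=6):
        out = []
        for _ in range(n):
            labels_top = np.repeat(["a", "b"], 20)
            labels_mid = np.repeat(["a1", "a2", "b1", "b2"], 10)
            X = rng.standard_normal((40, 8, 4))
            if signal_level == "top":
                pattern = rng.standard_normal(8)
                X[labels_top == "b"] += 2.0 * pattern[None, :, None]
            frame = pd.DataFrame({"label_top": labels_top, "label_mid": labels_mid})
            out.append((make_features(X), frame))
        return out

    def test_signal_at_top_selects_top(self):
        rng = np.random.default_rng(18)
        parts = self._participants(rng, "top")
        cfg = DecoderConfig(metric="accuracy", n_repetitions=1,
                            n_label_shuffles=8, shuffle_repetitions=1, seed=0)
        sel, results, stats = level_selection(parts, cfg, StatConfig(),
                                              levels=("top", "mid"))
        assert sel == "top"
        assert results["top"].chance == 0.5
        assert results["mid"].chance == 0.25
        assert stats["top"].significant.any()

    def test_null_selects_fewest_classes_with_no_significance(self):
        rng = np.random.default_rng(19)
        parts = self._participants(rng, None)
        cfg = DecoderConfig(metric="accuracy", n_repetitions=1,
                            n_label_shuffles=8, shuffle_repetitions=1, seed=0)
        sel, _, stats = level_selection(parts, cfg, StatConfig(),
                                        levels=("top", "mid"))
        assert sel == "top"     # tie on zero significant windows -> fewest classes

    def test_missing_level_labels_error(self):
        rng = np.random.default_rng(20)
        parts = self._participants(rng)
        cfg = DecoderConfig(metric="accuracy", n_repetitions=1,
                            n_label_shuffles=4, shuffle_repetitions=1, seed=0)
        with pytest.raises(ValueError, match="missing"):
            level_selection(parts, cfg, levels=("top", "mid", "bot"))
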