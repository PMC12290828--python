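"""Two-level permutation, Wilcoxon contrasts, BY-FDR, and the supplementary
simulations, checked against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from pingdecode.stats import (StatConfig, fdr_dependent,
                              intertrial_variance_contrast,
                              trial_count_pvalue_simulation,
                              two_level_permutation, wilcoxon_contrast)

from conftest import make_epochs


def by_stepup_oracle(p):
    """Literal Benjamini-Yekutieli step-up: q_i = min_{j>=i} c(m)*m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    adj_sorted = c_m * m * p[order] / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def signed_rank_enumeration_p(d, alternative="greater"):
    """Exact Wilcoxon signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    count = 0
    total = 2 ** n
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if alternative == "greater":
            count += w >= w_obs
        elif alternative == "less":
            count += w <= w_obs
        else:
            mu = ranks.sum() / 2.0
            count += abs(w - mu) >= abs(w_obs - mu) - 1e-12
    return count / total


class TestTwoLevelPermutation:
    def test_add_one_convention_extreme_observation(self):
        empirical = np.full((4, 1), 10.0)
        first_level = np.zeros((4, 5, 1))
        res = two_level_permutation(empirical, first_level,
                                    StatConfig(n_second_level=999, seed=0))
        assert np.isclose(res.p_raw[0], 1.0 / 1000.0)

    def test_observation_at_null_median(self):
        rng = np.random.default_rng(0)
        first_level = rng.standard_normal((6, 40, 1))
        empirical = first_level.mean(axis=1) * 0.0   # group mean 0 = null centre
        res = two_level_permutation(empirical, first_level,
                                    StatConfig(n_second_level=4000, seed=1))
        assert abs(res.p_raw[0] - 0.5) < 0.05

    def test_matches_exhaustive_enumeration_small(self):
        """3 participants x 4 permutations: all 64 combinations enumerable."""
        rng = np.random.default_rng(2)
        first_level = rng.standard_normal((3, 4, 2))
        empirical = rng.standard_normal((3, 2))
        obs = empirical.mean(axis=0)
        for w in range(2):
            nulls = [np.mean([first_level[0, i, w], first_level[1, j, w],
                              first_level[2, k, w]])
                     for i in range(4) for j in range(4) for k in range(4)]
            exact_frac = np.mean(np.asarray(nulls) >= obs[w])
            res = two_level_permutation(empirical, first_level,
                                        StatConfig(n_second_level=40_000, seed=3))
            # MC estimate of the same exceedance fraction
            mc_frac = res.p_raw[w] * 40_001 / 40_000 - 1.0 / 40_000
            se = np.sqrt(exact_frac * (1 - exact_frac) / 40_000) + 1e-4
            assert abs(mc_frac - exact_frac) < 4 * se

    def test_window_restriction_before_fdr(self):
        rng = np.random.default_rng(4)
        first_level = rng.standard_normal((5, 10, 6))
        empirical = rng.standard_normal((5, 6))
        times = np.arange(6) * 100.0
        cfg = StatConfig(n_second_level=200, seed=0, analysis_window_ms=(200.0, 400.0))
        res = two_level_permutation(empirical, first_level, cfg, window_times=times)
        assert np.array_equal(res.window_times, [200.0, 300.0, 400.0])
        assert res.p_raw.size == 3

    def test_empty_analysis_window_errors(self):
        with pytest.raises(ValueError, match="no windows"):
            two_level_permutation(np.zeros((3, 2)), np.zeros((3, 2, 2)),
                                  StatConfig(analysis_window_ms=(1e4, 2e4)),
                                  window_times=np.array([0.0, 100.0]))

    def test_reproducible_and_never_zero(self):
        rng = np.random.default_rng(5)
        fl = rng.standard_normal((4, 6, 3))
        emp = rng.standard_normal((4, 3)) + 3.0
        cfg = StatConfig(n_second_level=500, seed=11)
        a = two_level_permutation(emp, fl, cfg)
        b = two_level_permutation(emp, fl, cfg)
        assert np.array_equal(a.p_raw, b.p_raw)
        assert (a.p_raw > 0).all()


class TestWilcoxonContrast:
    def test_identical_inputs_give_p_one(self):
        a = np.tile(np.arange(6, dtype=float)[:, None], (1, 2))
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_contrast(a, a, StatConfig(sided="greater"))
        assert (res.p_raw == 1.0).all()

    def test_constant_positive_shift_n29(self):
        rng = np.random.default_rng(6)
        b = rng.standard_normal((29, 1))
        res = wilcoxon_contrast(b + 1e3, b, StatConfig(sided="greater"))
        assert res.p_raw[0] < 0.001

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        a = rng.standard_normal((n, 1))
        b = rng.standard_normal((n, 1))
        res = wilcoxon_contrast(a, b, StatConfig(sided="greater"))
        oracle = signed_rank_enumeration_p((a - b)[:, 0], "greater")
        assert np.isclose(res.p_raw[0], oracle, atol=1e-10)

    def test_null_p_uniform_over_replicates(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(300):
            a = rng.standard_normal((10, 1))
            b = rng.standard_normal((10, 1))
            ps.append(wilcoxon_contrast(a, b, StatConfig(sided="greater")).p_raw[0])
        # discrete exact test: distribution is sub-uniform but close
        assert kstest(ps, "uniform").pvalue > 1e-4
        assert abs(np.mean(ps) - 0.5) < 0.06

    def test_too_few_participants_errors(self):
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_contrast(np.zeros((3, 2)), np.ones((3, 2)))


class TestFDRDependent:
    def test_single_p_unchanged(self):
        assert np.isclose(fdr_dependent(np.array([0.037]))[0], 0.037)

    def test_four_p_literal_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adjusted = fdr_dependent(p)
        # c(4) = 25/12; q_i = min_j>=i (25/12)*4*p_j/j = 1/12 for every i here
        assert np.allclose(adjusted, 1.0 / 12.0, atol=1e-12)
        assert np.allclose(adjusted, by_stepup_oracle(p), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepup_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(2, 40)))
        assert np.allclose(fdr_dependent(p), by_stepup_oracle(p), atol=1e-12)

    def test_all_ones_and_idempotence(self):
        p = np.ones(5)
        assert np.allclose(fdr_dependent(p), 1.0)
        rng = np.random.default_rng(9)
        q = fdr_dependent(rng.uniform(0.001, 1.0, 12))
        assert np.allclose(fdr_dependent(q), q, atol=1e-12)

    def test_adjusted_never_below_raw_and_empty(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.001, 1.0, 9)
        assert (fdr_dependent(p) >= p - 1e-15).all()
        assert fdr_dependent(np.array([])).size == 0


class TestTrialCountSimulation:
    def test_tiny_grid_runs_and_reports(self):
        df = trial_count_pvalue_simulation(effect="absent", trial_grid=(20, 40),
                                           n_participants=4, n_channels=6,
                                           n_windows=3, n_second_level=200,
                                           n_label_shuffles=6, seed=0)
        assert set(df["n_trials"]) == {20, 40}
        assert ((df["median_p"] > 0) & (df["median_p"] <= 1)).all()

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            trial_count_pvalue_simulation(effect="maybe")


class TestIntertrialVariance:
    def _epochs(self, rng, scale, n_trials=20):
        return make_epochs(rng.standard_normal((n_trials, 3, 50)) * scale,
                           tmin=0.0)

    def test_identical_conditions_p_one(self):
        rng = np.random.default_rng(11)
        eps = [self._epochs(rng, 1.0) for _ in range(6)]
        with pytest.warns(UserWarning, match="zero"):
            df = intertrial_variance_contrast(eps, eps, window_ms=(0.0, 190.0))
        assert (df["p_raw"] == 1.0).all()

    def test_regularised_condition_has_lower_variance(self):
        rng = np.random.default_rng(12)
        ping = [self._epochs(rng, 0.5) for _ in range(8)]
        noping = [self._epochs(rng, 1.0) for _ in range(8)]
        df = intertrial_variance_contrast(ping, noping, window_ms=(0.0, 190.0),
                                          cfg=StatConfig(sided="less"))
        assert (df["var_ping"] < df["var_noping"]).all()
        assert (df["p_fdr"] < 0.05).all()

    def test_single_trial_condition_errors(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="2 trials"):
            intertrial_variance_contrast([self._epochs(rng, 1.0, n_trials=1)],
                                         [self._epochs(rng, 1.0)])
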