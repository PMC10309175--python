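"""Unit tests for the shared statistical kernels."""

import math
import warnings
from itertools import combinations

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from steroidmir.stats import (
    DegenerateInputError,
    auc_rank,
    bh_adjust,
    fit_logistic,
    fit_lmm_random_intercept,
    hypergeom_upper,
    wald_p,
)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = np.ones((100, 1))
        fit = fit_logistic(X, y)
        assert fit.coefs[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-6)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # poor&high=40, poor&low=10, good&high=20, good&low=30
        y = np.r_[np.ones(50), np.zeros(50)]
        x = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
        fit = fit_logistic(np.column_stack([np.ones(100), x]), y)
        assert fit.coefs[1] == pytest.approx(math.log(6.0), abs=1e-6)

    def test_constant_outcome_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_logistic(np.ones((3, 1)), np.array([0.0, 1.0, 2.0]))

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20), np.arange(20)])
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(DegenerateInputError):
            fit_logistic(X, y)

    def test_matches_newton_oracle(self):
        """Textbook Newton-Raphson on random small datasets, 1e-6 agreement."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 80
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            beta_true = rng.normal(0, 0.8, size=3)
            p = 1 / (1 + np.exp(-X @ beta_true))
            y = (rng.random(n) < p).astype(float)
            if y.min() == y.max():
                continue
            beta = np.zeros(3)
            for _ in range(50):
                mu = 1 / (1 + np.exp(-X @ beta))
                W = mu * (1 - mu)
                H = X.T @ (X * W[:, None])
                g = X.T @ (y - mu)
                beta = beta + np.linalg.solve(H, g)
            fit = fit_logistic(X, y)
            np.testing.assert_allclose(fit.coefs, beta, atol=1e-6)

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = fit_logistic(np.column_stack([np.ones(20), x]), y)
        assert fit.separated and not fit.converged


class TestLmm:
    def test_matches_mixedlm_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            g = np.repeat(np.arange(40), 3)
            X = np.column_stack([np.ones(120), rng.normal(size=120)])
            y = X @ [1.0, 0.5] + rng.normal(0, 1, 40)[g] + rng.normal(0, 0.8, 120)
            fit = fit_lmm_random_intercept(X, y, g)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sm.MixedLM(y, X, groups=g).fit(reml=True)
            np.testing.assert_allclose(fit.coefs, np.asarray(ref.fe_params), atol=1e-4)
            assert fit.re_var == pytest.approx(
                float(np.asarray(ref.cov_re).ravel()[0]), abs=1e-3
            )
            assert fit.resid_var == pytest.approx(float(ref.scale), abs=1e-3)

    def test_zero_variance_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        g = np.repeat(np.arange(50), 2)
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = X @ [0.3, 1.2] + rng.normal(0, 1, 100)  # no group effect
        fit = fit_lmm_random_intercept(X, y, g)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefs, ols, atol=1e-5)

    def test_singleton_groups_are_ols_with_zero_re(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ [1.0, -0.5] + rng.normal(size=30)
        fit = fit_lmm_random_intercept(X, y, np.arange(30))
        assert fit.re_var == 0.0
        np.testing.assert_allclose(
            fit.coefs, np.linalg.lstsq(X, y, rcond=None)[0], atol=1e-10
        )

    def test_variance_recovery_balanced(self):
        """Planted intercept SD 1 and residual SD 1 at 200 groups."""
        re_vars, res_vars = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            g = np.repeat(np.arange(200), 2)
            X = np.column_stack([np.ones(400), rng.normal(size=400)])
            y = X @ [0.5, 1.0] + rng.normal(0, 1, 200)[g] + rng.normal(0, 1, 400)
            fit = fit_lmm_random_intercept(X, y, g)
            re_vars.append(fit.re_var)
            res_vars.append(fit.resid_var)
        assert abs(np.median(re_vars) - 1.0) < 0.2
        assert abs(np.median(res_vars) - 1.0) < 0.2

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(DegenerateInputError):
            fit_lmm_random_intercept(X, np.zeros(10), np.repeat([0, 1], 5))


class TestHypergeom:
    def test_single_term(self):
        assert hypergeom_upper(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_k_zero_is_one(self):
        assert hypergeom_upper(30, 7, 11, 0) == 1.0

    def test_matches_scipy_all_small_universes(self):
        for N in range(1, 21):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        ours = hypergeom_upper(N, K, n, k)
                        ref = sps.hypergeom.sf(k - 1, N, K, n)
                        assert ours == pytest.approx(ref, rel=1e-10, abs=1e-12)

    def test_matches_enumeration(self):
        """Count draws directly for a handful of tiny configurations."""
        for N, K, n in [(6, 3, 3), (8, 4, 5), (10, 5, 4), (12, 6, 6)]:
            success = set(range(K))
            for k in range(min(K, n) + 1):
                count = sum(
                    1 for draw in combinations(range(N), n)
                    if len(success.intersection(draw)) >= k
                )
                assert hypergeom_upper(N, K, n, k) == pytest.approx(
                    count / math.comb(N, n)
                )

    def test_monotone_in_k(self):
        ps = [hypergeom_upper(40, 15, 12, k) for k in range(13)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_arguments(self):
        with pytest.raises(ValueError):
            hypergeom_upper(10, 12, 5, 0)
        with pytest.raises(ValueError):
            hypergeom_upper(10, 5, 5, 6)


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_step_up_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestAucRank:
    def test_hand_example(self):
        assert auc_rank([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc_rank([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert auc_rank([1.0] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.4).astype(int)
        assert auc_rank(s, y) == pytest.approx(auc_rank(np.exp(s), y))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            auc_rank([1, 2], [1, 1])


class TestWaldP:
    def test_zero_gives_one(self):
        assert wald_p(0.0) == 1.0

    def test_symmetric(self):
        assert wald_p(1.7) == pytest.approx(wald_p(-1.7))

    def test_matches_normal_sf(self):
        assert wald_p(1.96) == pytest.approx(2 * sps.norm.sf(1.96))
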