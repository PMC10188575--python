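import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from uafit import (
    bvn_cdf,
    dichotomize,
    gamma_pearson,
    gamma_tetrachoric,
    pearson_correlations,
    tetrachoric_correlations,
    unvech_off,
)
from uafit.correlations import _solve_tetrachoric, _upper_quadrant


class TestPearson:
    def test_perfect_correlation_is_boundary(self, rng):
        x = rng.normal(size=200)
        est = pearson_correlations(np.column_stack([x, x]))
        assert est.r[0] == pytest.approx(1.0)

    def test_constant_column_named_in_error(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="v2"):
            pearson_correlations(X)

    def test_missing_values_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        X[3, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pearson_correlations(X)

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(100, 3))
        perm = rng.permutation(100)
        assert pearson_correlations(X).r == pytest.approx(
            pearson_correlations(X[perm]).r
        )

    def test_negative_noisy_closed_form(self, rng):
        # x2 = -x1 + noise(sd sigma): rho = -1/sqrt(1+sigma^2)
        sigma = 0.8
        n = 200_000
        x1 = rng.normal(size=n)
        x2 = -x1 + sigma * rng.normal(size=n)
        est = pearson_correlations(np.column_stack([x1, x2]))
        assert est.r[0] == pytest.approx(-1 / np.sqrt(1 + sigma**2), abs=0.005)


class TestBvnCdf:
    def test_against_scipy_mvn(self):
        grid = [-1.5, -0.3, 0.0, 0.8, 2.0]
        for h, k, rho in itertools.product(grid, grid, [-0.9, -0.45, 0.0, 0.3, 0.85]):
            ref = multivariate_normal(
                mean=[0, 0], cov=[[1, rho], [rho, 1]]
            ).cdf([h, k])
            assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=5e-7), (h, k, rho)

    def test_degenerate_correlations(self):
        assert bvn_cdf(0.5, 1.0, 1.0) == pytest.approx(norm.cdf(0.5))
        assert bvn_cdf(0.5, -0.7, -1.0) == pytest.approx(
            max(0.0, norm.cdf(0.5) + norm.cdf(-0.7) - 1)
        )


class TestTetrachoric:
    def test_balanced_independent_table_gives_zero(self):
        # counts (25, 25, 25, 25)
        X = np.array([[1, 1], [1, 0], [0, 1], [0, 0]] * 25, dtype=float)
        est = tetrachoric_correlations(X)
        assert est.r[0] == pytest.approx(0.0, abs=1e-10)

    def test_grid_search_oracle_40_10_10_40(self):
        # 2x2 counts (n11, n10, n01, n00) = (40, 10, 10, 40)
        X = np.array([[1, 1]] * 40 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 40,
                     dtype=float)
        est = tetrachoric_correlations(X)
        # brute-force grid over the multinomial likelihood
        ta = tb = norm.ppf(0.5)
        grid = np.linspace(-0.99, 0.99, 3961)
        best = None
        for rho in grid:
            p11 = _upper_quadrant(ta, tb, rho)
            p1 = 1 - norm.cdf(ta)
            p10 = p1 - p11
            p01 = p1 - p11
            p00 = 1 - p10 - p01 - p11
            if min(p11, p10, p01, p00) <= 0:
                continue
            ll = 40 * np.log(p11) + 10 * np.log(p10) + 10 * np.log(p01) + 40 * np.log(p00)
            if best is None or ll > best[0]:
                best = (ll, rho)
        assert est.r[0] == pytest.approx(best[1], abs=1e-4)

    def test_ml_score_solved_to_tolerance(self, rng):
        X = dichotomize(rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], 500))
        est = tetrachoric_correlations(X)
        p11 = np.mean((X[:, 0] == 1) & (X[:, 1] == 1))
        ta, tb = est.thresholds
        assert abs(_upper_quadrant(ta, tb, est.r[0]) - p11) < 1e-8

    def test_mean_split_consistency_rho_05(self, rng):
        C = np.array([[1, 0.5], [0.5, 1]])
        X = dichotomize(rng.multivariate_normal([0, 0], C, 100_000))
        est = tetrachoric_correlations(X)
        assert est.r[0] == pytest.approx(0.5, abs=0.01)

    def test_monotone_column_rejected(self):
        X = np.column_stack([np.ones(20), np.r_[np.ones(10), np.zeros(10)]])
        with pytest.raises(ValueError, match="single category"):
            tetrachoric_correlations(X)

    def test_non_binary_rejected(self, rng):
        with pytest.raises(ValueError, match="coded"):
            tetrachoric_correlations(rng.normal(size=(30, 2)))

    def test_empty_cell_continuity_correction_warns(self):
        X = np.array([[1, 1]] * 12 + [[0, 0]] * 10 + [[1, 0]] * 5, dtype=float)
        with pytest.warns(UserWarning, match="continuity"):
            est = tetrachoric_correlations(X)
        assert np.isfinite(est.r[0]) and abs(est.r[0]) < 1


class TestGammaPearson:
    def test_single_pair_at_zero(self):
        G = gamma_pearson(np.eye(2))
        assert G.values[0, 0] == pytest.approx(1.0)

    def test_single_pair_at_half(self):
        # (1 - rho^2)^2 at rho = .5
        G = gamma_pearson(unvech_off(np.array([0.5]), 2))
        assert G.values[0, 0] == pytest.approx(0.5625)

    def test_three_variables_uncorrelated_gives_identity(self):
        G = gamma_pearson(np.eye(3))
        assert G.values == pytest.approx(np.eye(3))

    def test_matches_monte_carlo_covariance(self, rng, ref_pop):
        # n * Cov_MC(s) over 2000 replications vs the closed form, within 3 MC SE
        Sigma = ref_pop.Sigma0[:3, :3]
        n, reps = 300, 2000
        L = np.linalg.cholesky(Sigma)
        rs = np.empty((reps, 3))
        for b in range(reps):
            X = rng.standard_normal((n, 3)) @ L.T
            rs[b] = pearson_correlations(X).r
        mc = n * np.cov(rs.T)
        G = gamma_pearson(Sigma).values
        se = np.sqrt(
            (np.outer(np.diag(G), np.diag(G)) + G**2) / reps
        )  # var of a sample covariance, normal approx
        assert np.all(np.abs(mc - G) < 3 * se)

    def test_permutation_consistency(self, rng):
        # permuting variables permutes Gamma conformably
        from uafit import pair_indices
        A = rng.uniform(-0.4, 0.4, (4, 4))
        R = np.clip((A + A.T) / 2, -0.9, 0.9)
        np.fill_diagonal(R, 1.0)
        perm = [2, 0, 3, 1]
        Rp = R[np.ix_(perm, perm)]
        rows, cols = pair_indices(4)
        # map each pair of Rp back to the pair index in R
        def pid(i, j):
            i, j = max(i, j), min(i, j)
            return next(a for a, (r, c) in enumerate(zip(rows, cols)) if (r, c) == (i, j))
        idx = [pid(perm[i], perm[j]) for i, j in zip(rows, cols)]
        Gp = gamma_pearson(Rp).values
        G = gamma_pearson(R).values
        signs = np.ones(len(idx))  # correlations are symmetric in (i, j)
        assert np.allclose(Gp, G[np.ix_(idx, idx)] * np.outer(signs, signs))

    def test_psd(self, ref_pop):
        G = gamma_pearson(ref_pop.Sigma0)
        assert G.min_eigenvalue() > -1e-8


class TestGammaTetrachoric:
    def test_balanced_null_diagonal_is_pi_half_squared(self, rng):
        # mean-split of independent normals: asymptotic variance of the
        # tetrachoric estimate is (pi/2)^2 ~ 2.47, vs 1.0 for Pearson
        X = dichotomize(rng.standard_normal((200_000, 2)))
        est = tetrachoric_correlations(X)
        G = gamma_tetrachoric(X, est)
        assert G.values[0, 0] == pytest.approx((np.pi / 2) ** 2, rel=0.05)

    def test_matches_monte_carlo_covariance(self, rng, ref_pop):
        Sigma = ref_pop.Sigma0[:3, :3]
        n, reps = 500, 800
        L = np.linalg.cholesky(Sigma)
        rs = np.empty((reps, 3))
        Gs = np.zeros((3, 3))
        for b in range(reps):
            X = dichotomize(rng.standard_normal((n, 3)) @ L.T)
            est = tetrachoric_correlations(X)
            rs[b] = est.r
            Gs += gamma_tetrachoric(X, est).values
        mc = n * np.cov(rs.T)
        G = Gs / reps
        se = np.sqrt((np.outer(np.diag(G), np.diag(G)) + G**2) / reps)
        assert np.all(np.abs(mc - G) < 3 * se)

    def test_half_sample_consistency(self, rng, ref_pop):
        X = dichotomize(
            rng.multivariate_normal(np.zeros(8), ref_pop.Sigma0, 4000)
        )
        est1 = tetrachoric_correlations(X[:2000])
        est2 = tetrachoric_correlations(X[2000:])
        G1 = gamma_tetrachoric(X[:2000], est1).values
        G2 = gamma_tetrachoric(X[2000:], est2).values
        # agreement of the dominant scale within sampling error
        assert np.trace(G1) == pytest.approx(np.trace(G2), rel=0.15)
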