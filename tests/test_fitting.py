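import numpy as np
import pytest

from uafit import (
    GammaMatrix,
    ModelSpec,
    build_population_model,
    fit,
    gamma_pearson,
    gls_weight,
    independence_fit,
    pearson_correlations,
    residual_projector,
    sample_metric,
    simple_structure,
    ulsmv_adjust,
    unvech_off,
    vech_off,
)


def _random_corr(rng, p):
    A = rng.normal(size=(p, 2 * p))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestFit:
    def test_saturated_model_zero_discrepancy(self, rng):
        # p=3 one factor with 3 loadings: t = 3 = p(p-1)/2, df = 0
        spec = simple_structure(3, 1)
        assert spec.df == 0
        r = vech_off(_random_corr(rng, 3))
        r = np.abs(r)  # a positive manifold is exactly reproducible
        res = fit(spec, r, n=100, method="ULS")
        assert res.F == pytest.approx(0.0, abs=1e-10)
        assert res.T == pytest.approx(0.0, abs=1e-8)

    def test_exact_one_factor_recovery(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])
        spec = simple_structure(5, 1)
        s = vech_off(np.outer(lam, lam) + np.diag(1 - lam**2))
        for method in ("ML", "GLS", "ULS"):
            res = fit(spec, s, n=500, method=method)
            assert res.converged
            assert np.allclose(np.abs(res.theta_hat), lam, atol=1e-6), method
            assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_ml_and_gls_same_solution_different_minimum(self, rng):
        # ML and GLS share their solution asymptotically (as residuals vanish);
        # with a correctly specified model and large n the estimates coincide
        # while the minimized discrepancy values differ
        pop = build_population_model(1, 8, "I", 0.6, 0.0)
        spec = simple_structure(8, 1)
        n = 200_000
        X = sample_metric(pop, n, rng)
        s = pearson_correlations(X).r
        ml = fit(spec, s, n=n, method="ML")
        gls = fit(spec, s, n=n, method="GLS")
        assert np.allclose(np.abs(ml.theta_hat), np.abs(gls.theta_hat), atol=1e-4)
        assert ml.F > 0 and gls.F > 0 and ml.F != pytest.approx(gls.F, rel=1e-4)

    def test_uls_statistic_is_residual_sum(self, rng, ref_pop):
        spec = simple_structure(8, 1)
        X = sample_metric(ref_pop, 400, rng)
        est = pearson_correlations(X)
        res = fit(spec, est.r, n=400, method="ULS")
        assert res.T == pytest.approx(400 * np.sum(res.residuals**2), rel=1e-10)
        assert res.T_uls == pytest.approx(res.T)

    def test_gradient_small_at_optimum(self, rng, ref_pop):
        spec = simple_structure(8, 1)
        X = sample_metric(ref_pop, 400, rng)
        res = fit(spec, pearson_correlations(X).r, 400, method="ML")
        assert res.converged and res.grad_norm < 1e-6


class TestGlsWeight:
    def test_identity_input_gives_identity_weight(self):
        W = gls_weight(np.eye(4))
        assert W == pytest.approx(np.eye(6), abs=1e-12)

    def test_symmetric_for_random_pd(self, rng):
        S = _random_corr(rng, 5)
        W = gls_weight(S)
        assert np.allclose(W, W.T)
        assert np.linalg.eigvalsh(W)[0] > 0

    def test_quadratic_form_matrix_identity(self, rng):
        # (s-sigma)' W (s-sigma) = 1/2 tr[(S-Sig) S^-1 (S-Sig) S^-1] for
        # unit-diagonal perturbations
        p = 5
        S = _random_corr(rng, p)
        W = gls_weight(S)
        Sinv = np.linalg.inv(S)
        for _ in range(10):
            e = rng.uniform(-0.05, 0.05, p * (p - 1) // 2)
            E = unvech_off(e, p) - np.eye(p)  # symmetric, zero diagonal
            lhs = e @ W @ e
            rhs = 0.5 * np.trace(E @ Sinv @ E @ Sinv)
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_singular_matrix_rejected(self):
        S = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            gls_weight(S)


class TestResidualProjector:
    def test_idempotent_annihilates_jacobian(self, rng, ref_pop):
        spec = simple_structure(8, 1)
        res = fit(spec, ref_pop.sigma0, n=1000, method="ULS")
        for W in (None, gls_weight(unvech_off(ref_pop.sigma0, 8))):
            U = residual_projector(res.delta, W)
            assert np.allclose(U @ U, U, atol=1e-8)
            assert np.allclose(U @ res.delta, 0, atol=1e-8)
        # the orthogonal projector is symmetric with rank df
        U = residual_projector(res.delta)
        assert np.allclose(U, U.T)
        assert np.linalg.matrix_rank(U) == spec.df

    def test_rank_deficient_jacobian_rejected(self):
        delta = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            residual_projector(delta)


class TestUlsmv:
    def test_zero_parameter_model_uses_full_gamma(self, rng):
        G = np.diag(rng.uniform(0.5, 1.5, 6))
        base = independence_fit(rng.uniform(-0.3, 0.3, 6), 200, 4, method="ULS")
        adj = ulsmv_adjust(base, GammaMatrix(G, source="pearson-normal"))
        assert np.allclose(adj.U, np.eye(6))
        assert adj.d_star == pytest.approx(np.trace(G) ** 2 / np.trace(G @ G))

    def test_scalar_gamma_gives_dstar_equal_df(self, ref_pop):
        spec = simple_structure(8, 1)
        res = fit(spec, ref_pop.sigma0, n=1000, method="ULS")
        c = 0.7
        adj = ulsmv_adjust(res, GammaMatrix(c * np.eye(28), source="pearson-normal"))
        assert adj.d_star == pytest.approx(spec.df, rel=1e-10)
        assert adj.a == pytest.approx(c, rel=1e-10)

    def test_dstar_bounded_by_df(self, rng, ref_pop):
        spec = simple_structure(8, 1)
        X = sample_metric(ref_pop, 500, rng)
        est = pearson_correlations(X)
        res = fit(spec, est.r, 500, method="ULS")
        adj = ulsmv_adjust(res, gamma_pearson(est))
        assert 0 < adj.d_star <= spec.df + 1e-8

    def test_mean_of_adjusted_statistic_is_dstar(self, rng):
        # calibration of the MV adjustment under a correctly specified model
        pop = build_population_model(1, 6, "I", 0.55, 0.0)
        spec = simple_structure(6, 1)
        n, reps = 300, 500
        tadj, dstar = [], []
        for _ in range(reps):
            X = sample_metric(pop, n, rng)
            est = pearson_correlations(X)
            res = fit(spec, est.r, n, method="ULS")
            adj = ulsmv_adjust(res, gamma_pearson(est))
            tadj.append(adj.T_adj)
            dstar.append(adj.d_star)
        se = np.std(tadj, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(tadj) - np.mean(dstar)) < 3 * se

    def test_mean_of_ml_statistic_is_df(self, rng):
        pop = build_population_model(1, 6, "I", 0.55, 0.0)
        spec = simple_structure(6, 1)
        n, reps = 300, 500
        T = []
        for _ in range(reps):
            X = sample_metric(pop, n, rng)
            T.append(fit(spec, pearson_correlations(X).r, n, method="ML").T)
        se = np.std(T, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(T) - spec.df) < 3 * se


class TestIndependenceFit:
    def test_uls_baseline_is_squared_norm(self, rng):
        s = rng.uniform(-0.5, 0.5, 10)
        base = independence_fit(s, 100, 5, method="ULS")
        assert base.F == pytest.approx(float(s @ s))
        assert base.df == 10
        assert base.delta.shape == (10, 0)

    def test_ml_baseline_is_neg_logdet(self, rng):
        R = _random_corr(rng, 4)
        base = independence_fit(vech_off(R), 100, 4, method="ML")
        assert base.F == pytest.approx(-np.linalg.slogdet(R)[1])
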