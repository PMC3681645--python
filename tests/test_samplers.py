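"""Gibbs conditionals against closed forms, quadrature, and rejection oracles."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import invgamma, kstest, ks_2samp, norm

from ublu.datamodel import ExpressionMatrix, FactorModel
from ublu.model import PriorSpec
from ublu.samplers import (
    ChainState,
    _gibbs_scan_factor,
    factor_conditional,
    sample_factor_column,
    sample_score_column,
    sample_score_columns,
    sample_sigma2,
    sample_truncated_normal,
    score_conditional,
)
from ublu.subspace import fit_projection, in_feasible_set, project_factor


# ---------------------------------------------------------------------------
# truncated normal primitive
# ---------------------------------------------------------------------------

class TestTruncatedNormal:
    def test_untruncated_mean(self, rng):
        draws = [sample_truncated_normal(2.0, 4.0, -np.inf, np.inf, rng)
                 for _ in range(20000)]
        se = 2.0 / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 2.0) < 4 * se

    def test_half_normal_mean(self, rng):
        draws = [sample_truncated_normal(0.0, 1.0, 0.0, np.inf, rng)
                 for _ in range(20000)]
        target = np.sqrt(2 / np.pi)
        sd = np.sqrt(1 - target ** 2)
        assert abs(np.mean(draws) - target) < 4 * sd / np.sqrt(len(draws))

    def test_far_tail_matches_quadrature(self, rng):
        lo, hi = 8.0, 9.0
        draws = np.array([sample_truncated_normal(0.0, 1.0, lo, hi, rng)
                          for _ in range(20000)])
        assert draws.min() >= lo and draws.max() <= hi
        # quadrature oracle for the truncated first moment
        z, _ = integrate.quad(lambda x: norm.pdf(x), lo, hi)
        m1, _ = integrate.quad(lambda x: x * norm.pdf(x), lo, hi)
        m2, _ = integrate.quad(lambda x: x * x * norm.pdf(x), lo, hi)
        mean, var = m1 / z, m2 / z - (m1 / z) ** 2
        assert abs(draws.mean() - mean) < 5 * np.sqrt(var / draws.size)
        # distribution-level agreement
        cdf = lambda x: np.array([integrate.quad(norm.pdf, lo, v)[0] / z for v in np.atleast_1d(x)])
        assert kstest(draws[:2000], cdf).pvalue > 0.01

    def test_domain_errors(self, rng):
        with pytest.raises(ValueError):
            sample_truncated_normal(0.0, 1.0, 2.0, 2.0, rng)
        with pytest.raises(ValueError):
            sample_truncated_normal(0.0, -1.0, 0.0, 1.0, rng)


# ---------------------------------------------------------------------------
# projected factor conditional
# ---------------------------------------------------------------------------

def _state_from(M, A, sigma2, basis):
    D = M.shape[1] - 1
    T = np.column_stack([project_factor(basis.truncate(D), M[:, r])
                         for r in range(M.shape[1])])
    return ChainState(T=T, A=A.copy(), sigma2=sigma2, E=T.copy())


class TestFactorConditional:
    def test_no_data_limit_recovers_prior(self, rank3_mixture):
        M, A, Y = rank3_mixture
        basis = fit_projection(Y, K=3)
        state = _state_from(M, A, 0.5, basis)
        state.A[0] = 0.0  # factor 0 absent from every sample
        prior = PriorSpec(E=state.E, s2=3.0, nu=2.0, R_max=5)
        cond = factor_conditional(0, Y, state, basis, prior)
        np.testing.assert_allclose(cond.Gamma, 3.0 * np.eye(2), rtol=1e-10)
        np.testing.assert_allclose(cond.tau, prior.E[:, 0], rtol=1e-8)

    def test_matches_dense_matrix_oracle(self, rank3_mixture):
        M, A, Y = rank3_mixture
        basis = fit_projection(Y, K=3)
        sigma2, s2 = 0.3, 2.0
        state = _state_from(M, A, sigma2, basis)
        prior = PriorSpec(E=state.E, s2=s2, nu=2.0, R_max=5)
        r = 1
        cond = factor_conditional(r, Y, state, basis, prior)
        # dense oracle with explicit P Sigma^-1 P^T and per-sample eps sums
        sub = basis.truncate(state.dim)
        PSP = sub.P @ (np.eye(Y.n_genes) / sigma2) @ sub.P.T
        a_r = state.A[r]
        Gamma = np.linalg.inv((a_r @ a_r) * PSP + np.eye(2) / s2)
        M_cur = state.factor_matrix(basis)
        acc = np.zeros(2)
        for i in range(Y.n_samples):
            eps = (Y.values[:, i] - a_r[i] * sub.y_bar
                   - (M_cur @ state.A[:, i] - a_r[i] * M_cur[:, r]))
            acc += a_r[i] * (sub.P @ (eps / sigma2))
        tau = Gamma @ (acc + prior.E[:, r] / s2)
        np.testing.assert_allclose(cond.Gamma, Gamma, rtol=1e-8,
                                   atol=1e-12 * np.abs(Gamma).max())
        np.testing.assert_allclose(cond.tau, tau, rtol=1e-8)

    def test_generalized_least_squares_limit(self, rank3_mixture):
        """Noiseless data + vague prior: the conditional mean is the truth."""
        M, A, Y = rank3_mixture
        basis = fit_projection(Y, K=3)
        state = _state_from(M, A, 1e-6, basis)
        prior = PriorSpec(E=np.zeros_like(state.E), s2=1e8, nu=2.0, R_max=5)
        for r in range(3):
            cond = factor_conditional(r, Y, state, basis, prior)
            np.testing.assert_allclose(cond.tau, state.T[:, r], atol=1e-5)

    def test_reparametrization_identity(self, rank3_mixture):
        """sum_r a_{r,i} (back t_r) + ybar = M a_i under sum-to-one scores."""
        M, A, Y = rank3_mixture
        basis = fit_projection(Y, K=3)
        state = _state_from(M, A, 0.5, basis)
        sub = basis.truncate(state.dim)
        M_back = sub.back @ state.T  # back-projected factors minus ybar
        for i in range(Y.n_samples):
            lhs = M_back @ state.A[:, i] + sub.y_bar
            rhs = state.factor_matrix(basis) @ state.A[:, i]
            np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestSampleFactorColumn:
    def test_output_feasible(self, rank3_mixture, rng):
        M, A, Y = rank3_mixture
        basis = fit_projection(Y, K=3)
        state = _state_from(M, A, 0.5, basis)
        prior = PriorSpec(E=state.E, s2=5.0, nu=2.0, R_max=5)
        for _ in range(50):
            r = int(rng.integers(3))
            t_new = sample_factor_column(r, Y, state, basis, prior, rng)
            assert in_feasible_set(basis.truncate(state.dim), t_new, tol=1e-12)
            state.T[:, r] = t_new

    def test_unconstrained_moments(self, rank3_mixture, rng):
        """Wide feasible region: one scan equals an exact Gaussian draw
        because the collapsed conditional has independent coordinates."""
        M, A, Y = rank3_mixture
        basis = fit_projection(Y, K=3)
        state = _state_from(M, A, 0.4, basis)
        prior = PriorSpec(E=state.E, s2=5.0, nu=2.0, R_max=5)
        cond = factor_conditional(0, Y, state, basis, prior)
        draws = np.array([
            sample_factor_column(0, Y, state, basis, prior, rng)
            for _ in range(4000)
        ])
        sd = np.sqrt(np.diag(cond.Gamma))
        for d in range(2):
            assert abs(draws[:, d].mean() - cond.tau[d]) < 5 * sd[d] / np.sqrt(4000)
            assert np.isclose(draws[:, d].std(), sd[d], rtol=0.1)

    def test_active_constraint_matches_rejection_oracle(self, rng):
        """2-D toy with the positivity wall cutting the Gaussian."""
        G, N = 4, 40
        base = rng.uniform(1.0, 2.0, size=(G, N))
        Y = ExpressionMatrix.from_values(base)
        basis = fit_projection(Y, K=3)
        tau = project_factor(basis, np.maximum(basis.y_bar - 1.1, 0.05))
        Gamma = 0.35 * np.eye(2)
        # rejection oracle
        oracle = []
        while len(oracle) < 4000:
            z = tau + np.sqrt(0.35) * rng.standard_normal(2)
            if in_feasible_set(basis, z):
                oracle.append(z)
        oracle = np.array(oracle)
        assert len(oracle) > 0
        # Gibbs draws: 30 decorrelation scans per kept draw, common start
        draws = []
        for _ in range(1500):
            t = np.zeros(2)
            for _ in range(8):
                t = _gibbs_scan_factor(tau, Gamma, t, basis, rng)
            draws.append(t)
        draws = np.array(draws)
        for d in range(2):
            assert ks_2samp(draws[:, d], oracle[:, d]).pvalue > 0.01


# ---------------------------------------------------------------------------
# score conditionals
# ---------------------------------------------------------------------------

class TestScoreConditional:
    def test_exact_recovery_on_noiseless_data(self, rank3_mixture):
        M, A, Y = rank3_mixture
        model = FactorModel(M, A, 1e-4)
        for i in range(Y.n_samples):
            cond = score_conditional(i, Y, model)
            np.testing.assert_allclose(cond.mean, A[:2, i], atol=1e-8)

    def test_matches_scalar_formula(self, rng):
        G = 2
        M = np.array([[2.0, 0.5], [0.3, 1.5]])
        a = np.array([[0.7], [0.3]])
        y = M @ a[:, 0] + np.array([0.05, -0.02])
        Y = ExpressionMatrix.from_values(y[:, None])
        sigma2 = 0.4
        cond = score_conditional(0, Y, FactorModel(M, a, sigma2))
        mbar = M[:, 0] - M[:, 1]
        var = sigma2 / (mbar @ mbar)
        mean = (mbar @ (y - M[:, 1])) / (mbar @ mbar)
        assert cond.cov[0, 0] == pytest.approx(var)
        assert cond.mean[0] == pytest.approx(mean)

    def test_cov_scales_with_sigma2(self, rank3_mixture):
        M, A, Y = rank3_mixture
        c1 = score_conditional(0, Y, FactorModel(M, A, 0.5))
        c2 = score_conditional(0, Y, FactorModel(M, A, 1.5))
        np.testing.assert_allclose(c2.cov, 3.0 * c1.cov, rtol=1e-10)
        np.testing.assert_allclose(c2.mean, c1.mean, rtol=1e-10)


class TestSampleScores:
    def test_simplex_constraints_hold(self, rank3_mixture, rng):
        M, A, Y = rank3_mixture
        model = FactorModel(M, A, 0.5)
        A_new = sample_score_columns(Y, model, rng, mode="both")
        assert A_new.min() >= 0.0
        np.testing.assert_allclose(A_new.sum(axis=0), 1.0, atol=1e-12)

    def test_r2_matches_rejection_oracle(self, rng):
        G, N = 6, 1
        M = np.abs(rng.uniform(0.5, 2.0, size=(G, 2)))
        M[:3, 0] += 3.0
        M[3:, 1] += 3.0
        a_true = np.array([[0.6], [0.4]])
        y = M @ a_true[:, 0] + rng.normal(0, 0.5, G)
        Y = ExpressionMatrix.from_values(np.abs(y)[:, None])
        model = FactorModel(M, a_true, 0.8)
        cond = score_conditional(0, Y, model)
        mean, sd = float(cond.mean[0]), float(np.sqrt(cond.cov[0, 0]))
        oracle = []
        while len(oracle) < 5000:
            z = rng.normal(mean, sd)
            if 0.0 <= z <= 1.0:
                oracle.append(z)
        draws = np.array([
            sample_score_column(0, Y, model, rng)[0] for _ in range(5000)
        ])
        assert ks_2samp(draws, np.array(oracle)).pvalue > 0.01

    def test_concentration_at_true_scores(self, rank3_mixture, rng):
        M, A, Y = rank3_mixture
        model = FactorModel(M, A, 1e-6)  # near-zero noise
        draws = np.array([sample_score_columns(Y, model, rng) for _ in range(200)])
        np.testing.assert_allclose(draws.mean(axis=0), A, atol=1e-2)

    def test_ablation_modes_relax_constraints(self, rank3_mixture, rng):
        M, A, Y = rank3_mixture
        noisy = ExpressionMatrix.from_values(
            np.abs(Y.values + rng.normal(0, 1.0, Y.values.shape))
        )
        model = FactorModel(M, A, 1.0)
        a_pos = sample_score_columns(noisy, model, rng, mode="positivity_only")
        assert a_pos.min() >= 0.0
        assert np.abs(a_pos.sum(axis=0) - 1.0).max() > 1e-6
        a_sum = sample_score_columns(noisy, model, rng, mode="sum_to_one_only")
        np.testing.assert_allclose(a_sum.sum(axis=0), 1.0, atol=1e-10)
        a_none = sample_score_columns(noisy, model, rng, mode="none")
        assert np.abs(a_none.sum(axis=0) - 1.0).max() > 1e-6


# ---------------------------------------------------------------------------
# noise variance
# ---------------------------------------------------------------------------

class TestSigma2:
    def test_long_run_mean(self, rank3_mixture, rng):
        M, A, Y = rank3_mixture
        noisy = ExpressionMatrix.from_values(
            np.abs(Y.values + rng.normal(0, 0.3, Y.values.shape))
        )
        model = FactorModel(M, A, 1.0)
        resid = noisy.values - M @ A
        ssr_val = float((resid ** 2).sum())
        gn = noisy.values.size
        draws = np.array([sample_sigma2(noisy, model, rng) for _ in range(4000)])
        assert draws.min() > 0
        expected = (ssr_val / 2) / (gn / 2 - 1)
        assert abs(draws.mean() - expected) < 4 * draws.std() / np.sqrt(draws.size)

    def test_tiny_instance_matches_density(self, rng):
        Y = ExpressionMatrix.from_values(np.array([[2.0]]))
        model = FactorModel(np.array([[1.0]]), np.array([[1.0]]), 1.0)
        ssr_val = 1.0  # (2 - 1)^2
        draws = np.array([sample_sigma2(Y, model, rng) for _ in range(3000)])
        # closed-form oracle: InverseGamma(1/2, SSR/2)
        assert kstest(draws, invgamma(a=0.5, scale=ssr_val / 2).cdf).pvalue > 0.01


# ---------------------------------------------------------------------------
# Geweke-style joint consistency
# ---------------------------------------------------------------------------

def _batch_se(x, n_batches=40):
    x = np.asarray(x)
    means = [b.mean() for b in np.array_split(x, n_batches)]
    return np.std(means, ddof=1) / np.sqrt(n_batches)


def test_geweke_successive_conditional_consistency(rng):
    """Prior-simulation and posterior-chain pipelines agree in distribution.

    With sigma2 held fixed, (T, A, Y) sampled as prior x likelihood must match
    the stationary distribution of the chain that alternates the T and A
    conditionals with redraws of Y.
    """
    G, N, R = 6, 12, 3
    base = np.random.default_rng(42).uniform(3.0, 7.0, size=(G, N))
    basis = fit_projection(ExpressionMatrix.from_values(base), K=3)
    D = R - 1
    E = np.zeros((D, R))
    E[0, 1] = 0.8
    E[1, 2] = 0.8
    s2, sigma2 = 0.6, 0.09
    prior = PriorSpec(E=E, s2=s2, nu=2.0, R_max=5)

    def prior_T(rng):
        T = np.empty((D, R))
        for r in range(R):
            while True:
                t = E[:, r] + np.sqrt(s2) * rng.standard_normal(D)
                if in_feasible_set(basis, t):
                    T[:, r] = t
                    break
        return T

    def draw_Y(T, A, rng):
        M = basis.back[:, :D] @ T + basis.y_bar[:, None]
        return np.abs(M @ A + np.sqrt(sigma2) * rng.standard_normal((G, N)))

    n_iter = 3000
    # marginal-conditional: i.i.d. draws from prior x likelihood
    mc_t, mc_a = [], []
    for _ in range(n_iter):
        T = prior_T(rng)
        A = rng.dirichlet(np.ones(R), size=N).T
        mc_t.append(T[0, 0])
        mc_a.append(A[0, 0])
    # successive-conditional: Gibbs updates of T and A with Y redrawn
    T = prior_T(rng)
    A = rng.dirichlet(np.ones(R), size=N).T
    sc_t, sc_a = [], []
    for _ in range(n_iter):
        Yv = draw_Y(T, A, rng)
        Y = ExpressionMatrix.from_values(Yv)
        state = ChainState(T=T.copy(), A=A.copy(), sigma2=sigma2, E=E)
        for r in range(R):
            state.T[:, r] = sample_factor_column(r, Y, state, basis, prior, rng)
        T = state.T
        M = state.factor_matrix(basis)
        A = sample_score_columns(Y, FactorModel(M, A, sigma2), rng, mode="both")
        sc_t.append(T[0, 0])
        sc_a.append(A[0, 0])

    for mc, sc in ((mc_t, sc_t), (mc_a, sc_a)):
        mc, sc = np.asarray(mc), np.asarray(sc)
        se = np.hypot(mc.std() / np.sqrt(mc.size), _batch_se(sc))
        assert abs(mc.mean() - sc.mean()) < 6 * se
        se2 = np.hypot((mc ** 2).std() / np.sqrt(mc.size), _batch_se(sc ** 2))
        assert abs((mc ** 2).mean() - (sc ** 2).mean()) < 6 * se2
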