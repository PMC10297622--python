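import copy
import warnings

import numpy as np
import pandas as pd
import pytest

from tweediemix import (
    BlupResult,
    fit,
    global_matrices,
    marginal_covariance,
    marginal_mean,
    mean_components,
    predict_random_effects,
    score_components,
    scoring_step,
    standard_errors,
    update_dispersions,
    validate_and_index,
)
from tweediemix.simulator import (
    ctmm_reference_design,
    simulate_ctmm,
    simulate_tmcdre,
    tmcdre_reference_design,
)

from conftest import mc_draws, random_instance


def tweedie_irls(X, y, p, tol=1e-12, max_iter=200):
    """Textbook quasi-likelihood IRLS for a log-link Tweedie GLM (test oracle)."""
    beta = np.zeros(X.shape[1])
    const = np.flatnonzero(np.all(X == X[0], axis=0))
    if const.size:
        beta[const[0]] = np.log(max(y.mean(), 1e-10)) / X[0, const[0]]
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(eta)
        w = mu ** (2.0 - p)
        z = eta + (y - mu) / mu
        beta_new = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


class TestScoreComponents:
    def test_zero_at_conditional_means(self, small_data, small_params):
        """Replacing U, V, Y by their conditional means zeroes every block."""
        m = mean_components(small_data, small_params)
        data = copy.copy(small_data)
        data.y = marginal_mean(small_data, small_params, m)
        blup = BlupResult(
            U_hat=m.mu_i.copy(),
            V_hat=m.mu_i[small_data.sub_cluster] * m.mu_ij,
            d_i=np.zeros(small_data.n_clusters),
            d_ij=np.zeros(small_data.n_subclusters),
        )
        psi1, psi2, psi3 = score_components(data, small_params, blup, m)
        np.testing.assert_allclose(psi1, 0.0, atol=1e-12)
        np.testing.assert_allclose(psi2, 0.0, atol=1e-12)
        np.testing.assert_allclose(psi3, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_component_route_equals_matrix_route(self, seed):
        """The BLUP-substituted level scores stack to X'D Var(Y)^{-1}(Y-EY)."""
        data, params = random_instance(seed)
        m = mean_components(data, params)
        blup = predict_random_effects(data, params, m)
        psi_c = np.concatenate(score_components(data, params, blup, m))
        psi_m, S, V, J = global_matrices(data, params, m)
        scale = np.max(np.abs(psi_m)) + 1.0
        np.testing.assert_allclose(psi_c, psi_m, rtol=1e-8, atol=1e-8 * scale)

    def test_score_zero_at_mean_data(self, small_data, small_params):
        data = copy.copy(small_data)
        data.y = marginal_mean(small_data, small_params)
        psi, _, _, _ = global_matrices(data, small_params)
        np.testing.assert_allclose(psi, 0.0, atol=1e-10)


class TestGlobalMatrices:
    def test_information_identities(self, small_data, small_params):
        _, S, V, J = global_matrices(small_data, small_params)
        np.testing.assert_array_equal(V, -S)
        np.testing.assert_array_equal(J, V)
        # V is a Gram-type matrix: symmetric positive definite on full rank
        np.testing.assert_allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) > 0)

    def test_asymptotic_optimality_vs_independence_working_model(self):
        """Var from the optimal score is no larger (PSD order) than the
        sandwich of an independence-working-covariance moment estimator."""
        for seed in (1, 4):
            data, params = random_instance(seed, I_range=(4, 6))
            m = mean_components(data, params)
            X = data.stacked_design()
            mu = marginal_mean(data, params, m)
            D = mu[:, None] * X
            _, S, V, _ = global_matrices(data, params, m)
            opt = np.linalg.inv(V)
            # independence working model: W = diag(Var Y)
            G = np.zeros_like(V)
            M = np.zeros_like(V)
            for i, sl in enumerate(data.cluster_slices()):
                cov = marginal_covariance(data, params, i, m)
                w = 1.0 / np.diag(cov)
                Dw = D[sl] * w[:, None]
                G += Dw.T @ D[sl]
                M += Dw.T @ cov @ Dw
            Ginv = np.linalg.inv(G)
            sandwich = Ginv @ M @ Ginv
            eig = np.linalg.eigvalsh(sandwich - opt)
            assert eig.min() > -1e-8 * np.abs(eig).max()


class TestScoringStep:
    def test_fixed_point_at_root(self, small_data, small_params):
        data = copy.copy(small_data)
        data.y = marginal_mean(small_data, small_params)
        beta_new = scoring_step(data, small_params)
        np.testing.assert_allclose(beta_new, small_params.beta, atol=1e-9)

    def test_glm_degeneracy_matches_independent_irls(self, rng):
        """With sigma2 = tau2 = 0 and no group covariates the fit is a
        Tweedie quasi-likelihood GLM; compare against a hand-coded IRLS."""
        from tweediemix.simulator import sample_tweedie_cp

        n = 300
        x = rng.uniform(-1, 1, n)
        mu = np.exp(0.4 - 0.9 * x)
        y = sample_tweedie_cp(mu, 0.7, 1.5, rng)
        frame = pd.DataFrame(
            {
                "cluster": np.repeat(np.arange(15), 20).astype(str),
                "subcluster": np.repeat(np.arange(60), 5).astype(str),
                "y": y,
                "x": x,
            }
        )
        data = validate_and_index(frame, {"x": "observation"}, add_intercept=True)
        res = fit(data, 1.5, fix_sigma2=0.0, fix_tau2=0.0)
        X = np.column_stack([np.ones(n), x])
        beta_ref = tweedie_irls(X, y, 1.5)
        assert res.converged
        np.testing.assert_allclose(res.coef, beta_ref, atol=1e-6)

    def test_intercept_only_single_cluster(self, rng):
        y = rng.gamma(2.0, 1.0, size=30)
        frame = pd.DataFrame(
            {"cluster": "a", "subcluster": "b", "y": y}
        )
        data = validate_and_index(frame, {}, add_intercept=True)
        res = fit(data, 1.4, fix_sigma2=0.0, fix_tau2=0.0)
        assert res.coef[0] == pytest.approx(np.log(y.mean()), abs=1e-8)


class TestDispersionUpdates:
    def test_naive_double_loop_reference(self):
        """Vectorized adjusted-Pearson sums equal a naive re-summation."""
        data, params = random_instance(11)
        m = mean_components(data, params)
        blup = predict_random_effects(data, params, m)
        s2, t2, r2 = update_dispersions(data, params, blup, m)

        I = data.n_clusters
        mu_i, mu_ij, mu_ijk, w = m.mu_i, m.mu_ij, m.mu_ijk, m.w_ij
        s2_ref = 0.0
        t2_ref = 0.0
        r2_ref = 0.0
        for i in range(I):
            s2_ref += ((blup.U_hat[i] - mu_i[i]) ** 2 + blup.d_i[i]) / mu_i[i] ** 2
            subs = np.flatnonzero(data.sub_cluster == i)
            ti = 0.0
            ri = 0.0
            for j in subs:
                resid = blup.V_hat[j] - mu_ij[j] * blup.U_hat[i]
                corr = (
                    blup.d_i[i] * mu_ij[j] ** 2
                    + blup.d_ij[j]
                    - 2.0 * params.rho2 * blup.d_i[i] * w[j] * mu_ij[j] ** 2
                )
                ti += (resid**2 + corr) / (mu_i[i] * mu_ij[j] ** 2)
                obs = np.flatnonzero(data.obs_subcluster == j)
                rj = 0.0
                for k in obs:
                    rj += (data.y[k] - blup.V_hat[j] * mu_ijk[k]) ** 2 / (
                        mu_i[i] * mu_ij[j] * mu_ijk[k] ** params.p
                    ) + blup.d_ij[j] * mu_ijk[k] ** (2.0 - params.p) / (
                        mu_i[i] * mu_ij[j]
                    )
                ri += rj / obs.size
            t2_ref += ti / subs.size
            r2_ref += ri / subs.size
        assert s2 == pytest.approx(s2_ref / I, rel=1e-10)
        assert t2 == pytest.approx(t2_ref / I, rel=1e-10)
        assert r2 == pytest.approx(r2_ref / I, rel=1e-10)

    def test_sigma2_zero_when_predictions_match_prior(self, small_data, small_params):
        m = mean_components(small_data, small_params)
        blup = BlupResult(
            U_hat=m.mu_i.copy(),
            V_hat=m.mu_i[small_data.sub_cluster] * m.mu_ij,
            d_i=np.zeros(small_data.n_clusters),
            d_ij=np.zeros(small_data.n_subclusters),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s2, _, _ = update_dispersions(small_data, small_params, blup, m)
        assert s2 <= 1e-10  # floored zero

    def test_estimator_means_at_truth(self, rng):
        """Mean of the adjusted Pearson estimators over replicates at the
        true parameters recovers (sigma2, tau2, rho2)."""
        sim = simulate_tmcdre(tmcdre_reference_design(I=150), seed=77)
        data, params = sim.data, sim.params
        m = mean_components(data, params)
        R = 250
        vals = np.empty((R, 3))
        work = copy.copy(data)
        _, _, Y = mc_draws(data, params, R, rng)
        for r in range(R):
            work.y = Y[r]
            blup = predict_random_effects(work, params, m)
            vals[r] = update_dispersions(work, params, blup, m)
        truth = np.array([params.sigma2, params.tau2, params.rho2])
        se = vals.std(axis=0, ddof=1) / np.sqrt(R)
        assert np.all(np.abs(vals.mean(axis=0) - truth) < 3.5 * se)


class TestStandardErrors:
    def test_scalar_case(self):
        np.testing.assert_allclose(standard_errors(np.array([[-4.0]])), [0.5])

    def test_requires_negative_definite(self):
        with pytest.raises(np.linalg.LinAlgError):
            standard_errors(np.array([[2.0]]))


class TestFit:
    def test_recovers_truth_on_moderate_design(self):
        sim = simulate_tmcdre(tmcdre_reference_design(I=269), seed=12)
        res = fit(sim.data, 1.55)
        assert res.converged
        assert res.n_iter < 200
        assert res.score_inf_norm < 1e-6
        # estimates within 4 SE of generating values
        z = (res.coef - sim.params.beta) / res.se
        assert np.all(np.abs(z) < 4.0)

    def test_score_unbiased_at_truth(self, rng):
        """Mean of psi(beta_true) over simulated datasets is zero."""
        sim = simulate_tmcdre(tmcdre_reference_design(I=60), seed=5)
        data, params = sim.data, sim.params
        m = mean_components(data, params)
        R = 500
        _, _, Y = mc_draws(data, params, R, rng)
        work = copy.copy(data)
        psis = np.empty((R, params.beta.size))
        for r in range(R):
            work.y = Y[r]
            psis[r], _, _, _ = global_matrices(work, params, m)
        se = psis.std(axis=0, ddof=1) / np.sqrt(R)
        assert np.all(np.abs(psis.mean(axis=0)) < 3.5 * se)

    def test_consistency_bias_shrinks_with_clusters(self):
        reps = 6
        err = {}
        for I in (40, 160, 640):
            acc = 0.0
            for r in range(reps):
                sim = simulate_tmcdre(tmcdre_reference_design(I=I), seed=9000 + 13 * r)
                res = fit(sim.data, 1.55)
                acc += np.linalg.norm(res.coef - sim.params.beta)
            err[I] = acc / reps
        assert err[640] < err[160] < err[40]

    def test_ctmm_special_case(self):
        """All covariates at observation level: mu_i = mu_ij = 1 throughout."""
        sim = simulate_ctmm(ctmm_reference_design(I=120), seed=21)
        res = fit(sim.data, 1.55)
        assert res.converged
        m = mean_components(sim.data, res.params)
        np.testing.assert_array_equal(m.mu_i, 1.0)
        np.testing.assert_array_equal(m.mu_ij, 1.0)
        assert res.params.beta1.size == 0 and res.params.beta2.size == 0
        z = (res.coef - sim.params.beta) / res.se
        assert np.all(np.abs(z) < 4.0)

    def test_profile_index_grid_contract(self):
        """The heuristic p-grid search fits at every grid value and returns
        a member of the grid with finite positive scores near 1."""
        from tweediemix.estimation import profile_index_parameter

        sim = simulate_tmcdre(tmcdre_reference_design(I=120), seed=64)
        best, scores = profile_index_parameter(sim.data, grid=(1.2, 1.55, 1.9))
        assert set(scores) == {1.2, 1.55, 1.9}
        assert best in scores
        assert all(np.isfinite(v) and 0.3 < v < 3.0 for v in scores.values())

    def test_nonconvergence_reported(self):
        sim = simulate_tmcdre(tmcdre_reference_design(I=50), seed=2)
        res = fit(sim.data, 1.55, max_iter=2)
        assert not res.converged
        assert res.n_iter == 2
        assert len(res.trace) == 2
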