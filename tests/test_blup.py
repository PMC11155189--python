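"""BLUP engine checks against naively assembled dense formulas."""

import numpy as np
import pandas as pd
import pytest

import metblup as mb
from metblup.blup import (
    DENSE_CELL_LIMIT,
    PEVStructure,
    assemble_covariances,
    compute_M,
    estimate_beta,
    fit_blup,
    prior_pev,
)
from metblup.inference import build_model_spec, set_known_components


def _random_instance(seed=0, N=4, J=3, missing=2, replicates=1):
    """Small instance with missing cells and an optional duplicated plot."""
    rng = np.random.default_rng(seed)
    panel = mb.generate_markers(N, 40, seed=rng)
    rel = mb.compute_grm(panel)
    gi, ej = np.meshgrid(np.arange(N), np.arange(J), indexing="ij")
    df = pd.DataFrame(
        {
            "genotype": np.array(rel.genotype_ids)[gi.ravel()],
            "environment": [f"env{j+1}" for j in ej.ravel()],
            "value": rng.normal(10, 2, N * J),
        }
    )
    if missing:
        df = df.drop(df.index[rng.choice(N * J, missing, replace=False)])
    if replicates:
        extra = df.iloc[:replicates].copy()
        extra["value"] += rng.normal(size=replicates)
        df = pd.concat([df, extra], ignore_index=True)
    omega = 0.8 * np.eye(J) + 0.2
    vc = set_known_components(omega, rng.uniform(0.3, 1.2, J),
                              [f"env{j+1}" for j in range(J)])
    return build_model_spec(df, rel), vc


def _naive(spec, vc):
    N, J, n = spec.n_genotypes, spec.n_environments, spec.n_obs
    Sg = np.kron(vc.omega_G, spec.A)
    Z = np.zeros((n, N * J))
    Z[np.arange(n), spec.cell_idx] = 1.0
    Sy = Z @ Sg @ Z.T + np.diag(vc.sigma2_E[spec.env_idx])
    X = spec.design_X()
    Syi = np.linalg.inv(Sy)
    beta = np.linalg.solve(X.T @ Syi @ X, X.T @ Syi @ spec.y)
    M = Syi - Syi @ X @ np.linalg.solve(X.T @ Syi @ X, X.T @ Syi)
    ghat = beta[np.repeat(np.arange(J), N)] + Sg @ Z.T @ M @ spec.y
    P = Sg - Sg @ Z.T @ Syi @ Z @ Sg
    return Sg, Z, Sy, beta, M, ghat, P


class TestAgainstNaiveFormulas:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_covariances_beta_m_gebv_and_pev(self, seed):
        spec, vc = _random_instance(seed)
        Sg, Z, Sy, beta, M, ghat, P = _naive(spec, vc)
        handles = assemble_covariances(spec, vc)
        np.testing.assert_allclose(handles.sigma_y(), Sy, atol=1e-10)
        np.testing.assert_allclose(handles.sigma_g_zt(), Sg @ Z.T, atol=1e-10)
        np.testing.assert_allclose(estimate_beta(spec, vc), beta, atol=1e-8)
        m_op = compute_M(spec, vc)
        np.testing.assert_allclose(m_op.dense(), M, atol=1e-8)
        fit = fit_blup(spec, vc)
        N, J = spec.n_genotypes, spec.n_environments
        np.testing.assert_allclose(
            fit.G_hat.values, ghat.reshape(J, N).T, atol=1e-8
        )
        np.testing.assert_allclose(fit.pev.dense(), P, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_pev_contractions_match_dense_tensor(self, seed):
        spec, vc = _random_instance(seed, N=5, J=3)
        fit = fit_blup(spec, vc)
        N, J = 5, 3
        P = fit.pev.dense().reshape(J, N, J, N)
        np.testing.assert_allclose(fit.pev.diagonal, np.einsum("jiji->ij", P), atol=1e-9)
        np.testing.assert_allclose(
            fit.pev.within_genotype_env_mean, np.einsum("jiki->ij", P) / J, atol=1e-9
        )
        np.testing.assert_allclose(
            fit.pev.within_env_genotype_mean, np.einsum("jijk->ij", P) / N, atol=1e-9
        )
        np.testing.assert_allclose(
            fit.pev.grand_row_mean, np.einsum("jikl->ij", P) / (N * J), atol=1e-9
        )
        np.testing.assert_allclose(
            fit.pev.env_block_double_mean, np.einsum("jikl->jk", P) / N**2, atol=1e-9
        )
        r = np.array([1, 0, 3])
        cross = np.stack([P[j, :, j, r[j]] for j in range(J)], axis=1)
        np.testing.assert_allclose(fit.pev.cross_with_reference(r), cross, atol=1e-9)
        assert fit.pev.entry(2, 1, 4, 0) == pytest.approx(P[1, 2, 0, 4], abs=1e-10)


class TestAnnihilator:
    def test_mx_zero_and_translation_invariance(self):
        spec, vc = _random_instance(4)
        m_op = compute_M(spec, vc)
        X = spec.design_X()
        np.testing.assert_allclose(m_op.apply(X), 0.0, atol=1e-8)
        v = np.random.default_rng(0).normal(size=spec.n_obs)
        shift = X @ np.array([3.0, -1.0, 7.0])
        np.testing.assert_allclose(m_op.apply(v + shift), m_op.apply(v), atol=1e-8)


class TestBetaSpecialCases:
    def test_ols_collapse_without_genetic_covariance(self):
        """Zero genetic covariance and equal error variances give plain means."""
        spec, _ = _random_instance(5, missing=0, replicates=0)
        J = spec.n_environments
        vc = set_known_components(np.zeros((J, J)), np.full(J, 0.7),
                                  spec.environment_ids)
        beta = estimate_beta(spec, vc)
        for j in range(J):
            assert beta[j] == pytest.approx(spec.y[spec.env_idx == j].mean())

    def test_environment_shift_equivariance(self):
        spec, vc = _random_instance(6)
        beta0 = estimate_beta(spec, vc)
        spec.y = spec.y + 5.0 * (spec.env_idx == 1)
        beta1 = estimate_beta(spec, vc)
        assert beta1[1] - beta0[1] == pytest.approx(5.0, abs=1e-8)
        assert beta1[0] == pytest.approx(beta0[0], abs=1e-8)


class TestGEBVLimits:
    def test_noise_free_complete_design_interpolates(self):
        sc = mb.SimScenario(n_genotypes=6, n_environments=3, h2_base=1.0,
                            h2_jitter=0.0, seed=20)
        ds, rel = mb.simulate_met(sc, n_loci=80)
        spec = build_model_spec(ds, rel)
        fit = fit_blup(spec, ds.true_components)
        np.testing.assert_allclose(fit.G_hat.values, ds.true_G.values, atol=1e-4)
        assert np.abs(fit.pev.dense()).max() < 1e-4

    def test_unobserved_unrelated_genotype_shrinks_to_mean(self):
        rng = np.random.default_rng(21)
        rel = mb.RelationshipMatrix(np.eye(5), list("abcde"))
        df = pd.DataFrame(
            {
                "genotype": np.repeat(list("abcd"), 2),
                "environment": ["e1", "e2"] * 4,
                "value": rng.normal(size=8),
            }
        )
        spec = build_model_spec(df, rel)
        vc = set_known_components(0.5 * np.eye(2) + 0.5, [0.4, 0.4], ["e1", "e2"])
        fit = fit_blup(spec, vc)
        np.testing.assert_allclose(fit.G_hat.values[4], fit.beta_hat, atol=1e-10)

    def test_huge_error_variance_total_shrinkage(self):
        spec, vc = _random_instance(7, missing=0, replicates=0)
        J = spec.n_environments
        vc_big = set_known_components(vc.omega_G, np.full(J, 1e8), spec.environment_ids)
        fit = fit_blup(spec, vc_big)
        np.testing.assert_allclose(
            fit.G_hat.values, np.tile(fit.beta_hat, (spec.n_genotypes, 1)), atol=1e-4
        )


class TestPEVProperties:
    def test_prior_without_observations(self):
        spec, vc = _random_instance(8)
        P = prior_pev(spec, vc)
        np.testing.assert_allclose(P.dense(), np.kron(vc.omega_G, spec.A), atol=1e-12)

    def test_monotone_information(self):
        """Adding an observation never increases any diagonal PEV entry."""
        spec, vc = _random_instance(9, N=5, J=3, missing=4, replicates=0)
        fit_full = fit_blup(spec, vc)
        drop = spec.n_obs - 1
        import dataclasses

        smaller = dataclasses.replace(
            spec,
            y=spec.y[:drop],
            env_idx=spec.env_idx[:drop],
            geno_idx=spec.geno_idx[:drop],
        )
        fit_small = fit_blup(smaller, vc)
        assert (fit_full.pev.diagonal <= fit_small.pev.diagonal + 1e-9).all()

    def test_dense_materialization_threshold(self):
        N = DENSE_CELL_LIMIT // 2 + 1
        P = PEVStructure(np.eye(2), np.eye(N), np.zeros((2 * N, 0)))
        with pytest.raises(MemoryError):
            P.dense()

    def test_beta_uncertainty_correction_widens_pev(self):
        spec, vc = _random_instance(10)
        p0 = fit_blup(spec, vc).pev
        p1 = fit_blup(spec, vc, add_beta_uncertainty=True).pev
        assert (p1.diagonal >= p0.diagonal - 1e-10).all()
        assert np.linalg.eigvalsh(p1.dense())[0] > -1e-8


class TestConditionalMomentBackbone:
    """Simulate (G, y) jointly and verify the engine's conditional moments.

    Over repeated draws from the generative model, the prediction errors
    G - G_hat are uncorrelated with G_hat and their covariance equals
    P plus the fixed-effect correction (beta is estimated per draw).
    """

    def test_prediction_error_moments(self):
        rng = np.random.default_rng(22)
        N, J, S = 5, 3, 20000
        rel = mb.compute_grm(mb.generate_markers(N, 60, seed=23))
        omega = 0.6 * np.eye(J) + 0.4
        sigma2_e = np.array([0.8, 1.1, 0.5])
        vc = set_known_components(omega, sigma2_e, [f"env{j+1}" for j in range(J)])
        mu = np.array([10.0, 12.0, 9.0])

        L = np.linalg.cholesky(np.kron(omega, rel.A) + 1e-10 * np.eye(N * J))
        u = (rng.standard_normal((S, N * J)) @ L.T)  # env-major cells
        noise = rng.standard_normal((S, N * J)) * np.sqrt(
            np.repeat(sigma2_e, N)
        )
        y = np.repeat(mu, N) + u + noise  # complete single-plot design

        gi, ej = np.meshgrid(np.arange(N), np.arange(J), indexing="ij")
        df = pd.DataFrame(
            {
                "genotype": np.array(rel.genotype_ids)[gi.ravel()],
                "environment": [f"env{j+1}" for j in ej.ravel()],
                "value": 0.0,
            }
        )
        spec = build_model_spec(df, rel)
        fit = fit_blup(spec, vc, add_beta_uncertainty=True)
        # predictions are affine in y; build the linear map once
        from metblup.blup import _chol_sigma_y, _solve_gls, assemble_covariances
        from scipy.linalg import cho_solve

        handles = assemble_covariances(spec, vc)
        cy = _chol_sigma_y(handles)
        _, _, siX, xtsx = _solve_gls(spec, vc, cy=cy)
        X = spec.design_X()
        sgzt = handles.sigma_g_zt()
        order = np.argsort(spec.cell_idx)  # y drawn in cell order
        y_obs = y[:, spec.cell_idx]
        beta_hat = y_obs @ siX @ np.linalg.inv(xtsx).T
        resid = y_obs - beta_hat @ X.T
        ghat = beta_hat[:, np.repeat(np.arange(J), N)] + resid @ cho_solve(cy, sgzt.T)

        g_true = np.repeat(mu, N) + u
        err = g_true - ghat
        assert np.abs(err.mean(axis=0)).max() < 4 * err.std(axis=0).max() / np.sqrt(S)
        emp_cov = np.cov(err.T)
        P_corr = fit.pev.dense()
        scale = np.sqrt(np.outer(np.diag(P_corr), np.diag(P_corr))) + 1e-3
        assert (np.abs(emp_cov - P_corr) / scale).max() < 0.1
        # the uncorrected P (beta treated as known) must understate the error
        P_plain = fit_blup(spec, vc).pev.dense()
        assert np.diag(emp_cov).mean() > np.diag(P_plain).mean()
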