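"""Tests of the No-Geno / Geno-Exp / Geno-Exp-Var estimator families."""

import numpy as np
import pandas as pd
import pytest

import metblup as mb
from metblup.blup import ModelFit, fit_blup, prior_pev
from metblup.estimators import (
    DegenerateDenominatorError,
    blue_cell_table,
    geno_exp_estimates,
    geno_exp_var_estimates,
    mc_conditional_oracle,
    no_geno_estimates,
)
from metblup.inference import build_model_spec, set_known_components
from metblup.metrics import EnvBVMatrix, MetricConfig, metric_table


QUADRATIC = ["lin_binns", "env_variance", "ecovalence"]


class TestNoGeno:
    def test_complete_single_plot_equals_plain_metrics(self):
        rng = np.random.default_rng(0)
        N, J = 6, 4
        values = rng.normal(10, 2, (N, J))
        gi, ej = np.meshgrid(np.arange(N), np.arange(J), indexing="ij")
        df = pd.DataFrame(
            {
                "genotype": [f"g{i}" for i in gi.ravel()],
                "environment": [f"e{j}" for j in ej.ravel()],
                "value": values.ravel(),
            }
        )
        table = no_geno_estimates(df)
        expected = metric_table(
            EnvBVMatrix(values, [f"g{i}" for i in range(N)], [f"e{j}" for j in range(J)])
        )
        pd.testing.assert_frame_equal(table, expected.assign(), check_like=True)

    def test_replicate_plots_averaged(self):
        df = pd.DataFrame(
            {
                "genotype": ["a", "a", "b", "a", "b"],
                "environment": ["e1", "e1", "e1", "e2", "e2"],
                "value": [1.0, 3.0, 5.0, 2.0, 4.0],
            }
        )
        cells = blue_cell_table(df)
        np.testing.assert_allclose(cells.values, [[2.0, 2.0], [5.0, 4.0]])

    def test_missing_cell_imputed_with_environment_mean(self):
        df = pd.DataFrame(
            {
                "genotype": ["a", "b", "c", "a", "b", "c", "a", "b"],
                "environment": ["e1"] * 3 + ["e2"] * 3 + ["e3"] * 2,
                "value": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            }
        )
        cells = blue_cell_table(df)
        assert cells.values[2, 2] == pytest.approx(7.5)  # mean of observed e3

    def test_fully_missing_genotype_has_env_mean_profile(self):
        df = pd.DataFrame(
            {
                "genotype": ["a", "b"] * 3,
                "environment": np.repeat(["e1", "e2", "e3"], 2),
                "value": [1.0, 3.0, 4.0, 8.0, 2.0, 4.0],
            }
        )
        table = no_geno_estimates(df, genotype_ids=["a", "b", "ghost"])
        env_means = np.array([2.0, 6.0, 3.0])
        assert table.set_index("genotype").loc["ghost", "env_variance"] == pytest.approx(
            env_means.var(ddof=1)
        )

    def test_empty_environment_rejected(self):
        df = pd.DataFrame(
            {"genotype": ["a"], "environment": ["e1"], "value": [np.nan]}
        )
        with pytest.raises(ValueError):
            no_geno_estimates(df)


class TestGenoExp:
    def test_noise_free_complete_design_all_estimators_agree(self):
        sc = mb.SimScenario(
            n_genotypes=8, n_environments=3, h2_base=1.0, h2_jitter=0.0, seed=30
        )
        ds, rel = mb.simulate_met(sc, n_loci=100)
        spec = build_model_spec(ds, rel)
        fit = fit_blup(spec, ds.true_components)
        ng = no_geno_estimates(ds.phenotypes).set_index("genotype")
        ge = geno_exp_estimates(fit).set_index("genotype")
        gev = geno_exp_var_estimates(fit).set_index("genotype")
        for m in QUADRATIC + ["finlay_wilkinson", "average"]:
            np.testing.assert_allclose(ge[m], ng.loc[ge.index, m], atol=1e-4)
            np.testing.assert_allclose(gev[m], ge[m], atol=1e-4)

    def test_unrelated_unobserved_genotype_looks_perfectly_stable(self):
        """Without the variance term an unobserved, unrelated genotype sits at
        the environment means, i.e. zero estimated ecovalence; the full BLUP
        keeps its ecovalence clearly positive."""
        rng = np.random.default_rng(31)
        N, J = 12, 4
        A = np.eye(N + 1)
        panel_A = mb.compute_grm(mb.generate_markers(N, 150, seed=32)).A
        A[:N, :N] = panel_A
        rel = mb.RelationshipMatrix(A, [f"g{i}" for i in range(N + 1)])
        gi, ej = np.meshgrid(np.arange(N), np.arange(J), indexing="ij")
        df = pd.DataFrame(
            {
                "genotype": [f"g{i}" for i in gi.ravel()],
                "environment": [f"e{j}" for j in ej.ravel()],
                "value": rng.normal(10, 1.5, N * J),
            }
        )
        spec = build_model_spec(df, rel)
        vc = set_known_components(
            0.5 * np.eye(J) + 0.5, np.full(J, 1.0), [f"e{j}" for j in range(J)]
        )
        fit = fit_blup(spec, vc)
        ge = geno_exp_estimates(fit).set_index("genotype")
        gev = geno_exp_var_estimates(fit).set_index("genotype")
        observed_scale = ge.loc[[f"g{i}" for i in range(N)], "ecovalence"].mean()
        assert ge.loc[f"g{N}", "ecovalence"] < 0.05 * observed_scale
        assert gev.loc[f"g{N}", "ecovalence"] > observed_scale


class TestGenoExpVar:
    def test_dominates_geno_exp_elementwise(self, small_fit):
        fit, _, _ = small_fit
        ge = geno_exp_estimates(fit)
        gev = geno_exp_var_estimates(fit)
        for m in QUADRATIC:
            assert (gev[m].to_numpy() >= ge[m].to_numpy() - 1e-10).all()
        np.testing.assert_allclose(gev["average"], ge["average"])

    def test_degenerate_fw_denominator_raises(self):
        G = EnvBVMatrix(
            np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3)),
            ["a", "b", "c"],
            ["e1", "e2", "e3"],
        )  # equal environment means
        vc = set_known_components(np.zeros((3, 3)), np.zeros(3), ["e1", "e2", "e3"])
        rel = mb.RelationshipMatrix(np.eye(3), ["a", "b", "c"])
        fit = ModelFit(
            beta_hat=np.zeros(3), G_hat=G, pev=prior_pev(rel, vc),
            components=vc, spec=None,
        )
        with pytest.raises(DegenerateDenominatorError):
            geno_exp_var_estimates(fit)


class TestMonteCarloOracle:
    def test_zero_pev_reduces_to_plain_metrics(self, small_fit):
        fit, _, rel = small_fit
        vc0 = set_known_components(
            np.zeros((3, 3)), np.zeros(3), fit.G_hat.environment_ids
        )
        frozen = ModelFit(
            beta_hat=fit.beta_hat, G_hat=fit.G_hat, pev=prior_pev(rel, vc0),
            components=vc0, spec=fit.spec,
        )
        orc = mc_conditional_oracle(frozen, n_draws=200, seed=0)
        expected = metric_table(fit.G_hat)
        # a hair of diagonal jitter is used to factor the zero matrix
        for m in QUADRATIC + ["average", "finlay_wilkinson"]:
            np.testing.assert_allclose(orc.table[m], expected[m], atol=1e-6)
            np.testing.assert_allclose(orc.standard_errors[m], 0.0, atol=1e-6)

    def test_taylor_error_shrinks_with_information(self):
        """The Finlay-Wilkinson ratio approximation error must fall as the
        PEV terms shrink (here: smaller error variances)."""
        errors = {}
        for tag, noise in (("weak", 1.0), ("strong", 0.01)):
            sc = mb.SimScenario(n_genotypes=6, n_environments=3, seed=33)
            ds, rel = mb.simulate_met(sc, n_loci=80)
            vc = set_known_components(
                ds.true_components.omega_G,
                ds.true_components.sigma2_E * noise,
                ds.true_components.environment_ids,
            )
            spec = build_model_spec(ds, rel)
            fit = fit_blup(spec, vc)
            closed = geno_exp_var_estimates(fit)["finlay_wilkinson"]
            orc = mc_conditional_oracle(fit, n_draws=40000, seed=34)
            errors[tag] = np.abs(closed - orc.table["finlay_wilkinson"]).max()
        assert errors["strong"] < errors["weak"]
        assert errors["strong"] < 1e-3

    def test_oracle_rejects_large_instances(self, small_fit):
        fit, _, _ = small_fit
        big = EnvBVMatrix(
            np.zeros((300, 10)) + np.arange(10)[None, :],
            [f"g{i}" for i in range(300)],
            [f"e{j}" for j in range(10)],
        )
        doctored = ModelFit(
            beta_hat=np.zeros(10), G_hat=big, pev=fit.pev,
            components=fit.components, spec=None,
        )
        with pytest.raises(ValueError):
            mc_conditional_oracle(doctored, n_draws=10, seed=0)
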