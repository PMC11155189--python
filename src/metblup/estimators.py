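"""The three GE-metric estimator families.

* ``no_geno``: the traditional phenotype-only estimator — per-cell BLUEs
  (plot means), with missing genotype-environment cells imputed by the
  environment mean of the observed values, fed to the plain metric formulas.
* ``geno_exp``: the squared-expectation term of the metric BLUPs — the plain
  metric formulas applied to env-GEBVs.
* ``geno_exp_var``: the full BLUP of each metric.  By the Koenig-Huygens
  split ``E(Q^2 | y) = [E(Q | y)]^2 + Var(Q | y)``, each squared-deviation
  metric gains a variance term assembled from contractions of the
  prediction-error-variance structure ``P``:

      L_i: + (1/2J) sum_j (P_{ij,ij} + P_{r_j j, r_j j} - 2 P_{ij, r_j j})
      S_i: + (1/(J-1)) sum_j (P_{ij,ij} - (1/J) sum_j' P_{ij,ij'})
      W_i: + sum_j (P_{ij,ij} - rowmean_j' - 2 colmean_i' + envblock_jj
                    + 2 grandrowmean - envblockmean_j)
      B_i: ratio of (expectation + PEV-correction) terms, a first-order
           Taylor approximation of the BLUP of the ratio.

  The Average has no variance term: its BLUP is the row mean of the
  env-GEBVs, identical under ``geno_exp`` and ``geno_exp_var``.

``mc_conditional_oracle`` verifies the closed forms by brute force: it draws
the env-BVs from their conditional Gaussian ``N(G_hat, P)`` and averages the
plain metrics over draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .blup import ModelFit
from .metrics import EnvBVMatrix, MetricConfig, metric_table

__all__ = [
    "ESTIMATOR_LABELS",
    "no_geno_estimates",
    "geno_exp_estimates",
    "geno_exp_var_estimates",
    "mc_conditional_oracle",
    "blue_cell_table",
]

ESTIMATOR_LABELS = ("no_geno", "geno_exp", "geno_exp_var")


class DegenerateDenominatorError(ValueError):
    """The PEV-corrected Finlay-Wilkinson denominator is nonpositive."""


def blue_cell_table(
    phenotypes, genotype_ids=None, environment_ids=None
) -> EnvBVMatrix:
    """Phenotype-only cell table: plot means per observed cell, environment
    means of observed values for missing cells.

    ``phenotypes`` is a long-format DataFrame (or METDataset) with columns
    genotype/environment/value; an ``observed`` column, if present, filters
    rows.  The genotype universe defaults to the genotypes present in the
    data; passing ``genotype_ids`` extends it (fully unobserved genotypes are
    imputed at the environment means).
    """
    df = phenotypes.phenotypes if hasattr(phenotypes, "phenotypes") else phenotypes
    if "observed" in df.columns:
        df = df[df["observed"]]
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError("no observed phenotypes")
    if genotype_ids is None:
        genotype_ids = sorted(df["genotype"].unique())
    if environment_ids is None:
        environment_ids = sorted(df["environment"].unique())
    cells = df.groupby(["genotype", "environment"], sort=False)["value"].mean()
    table = cells.unstack("environment").reindex(
        index=genotype_ids, columns=environment_ids
    )
    if table.isna().all(axis=0).any():
        missing = table.columns[table.isna().all(axis=0)][0]
        raise ValueError(f"environment {missing!r} has no observations")
    table = table.fillna(table.mean(axis=0))
    return EnvBVMatrix(
        values=table.to_numpy(),
        genotype_ids=list(genotype_ids),
        environment_ids=list(environment_ids),
    )


def no_geno_estimates(
    phenotypes,
    cfg: MetricConfig | None = None,
    genotype_ids=None,
    environment_ids=None,
) -> pd.DataFrame:
    """Phenotype-only MetricTable (BLUE cells + environment-mean imputation)."""
    table = blue_cell_table(phenotypes, genotype_ids, environment_ids)
    return metric_table(table, cfg, label="no_geno")


def geno_exp_estimates(fit: ModelFit, cfg: MetricConfig | None = None) -> pd.DataFrame:
    """Squared-expectation estimator: plain metrics on the env-GEBVs."""
    return metric_table(fit.G_hat, cfg, label="geno_exp")


def geno_exp_var_estimates(fit: ModelFit, cfg: MetricConfig | None = None) -> pd.DataFrame:
    """Full-BLUP estimator: expectation terms plus PEV variance terms."""
    cfg = cfg or MetricConfig()
    ghat = fit.G_hat.values
    N, J = ghat.shape
    P = fit.pev

    d = P.diagonal  # N x J
    rg = P.within_genotype_env_mean  # N x J
    ce = P.within_env_genotype_mean  # N x J
    g = P.grand_row_mean  # N x J
    q2 = P.env_block_double_mean  # J x J
    q = np.diag(q2)
    qbar = q2.mean(axis=1)

    r = metrics.reference_genotypes(ghat, cfg)
    cross = P.cross_with_reference(r)  # N x J

    lin = metrics.lin_binns(ghat, cfg) + np.sum(d + d[r, np.arange(J)][None, :] - 2 * cross, axis=1) / (2 * J)
    env_var = metrics.environmental_variance(ghat) + np.sum(d - rg, axis=1) / (J - 1)
    ecov = metrics.ecovalence(ghat) + np.sum(
        d - rg - 2 * ce + q[None, :] + 2 * g - qbar[None, :], axis=1
    )

    env_dev = ghat.mean(axis=0) - ghat.mean()
    row_dev = ghat - ghat.mean(axis=1, keepdims=True)
    fw_num = row_dev @ env_dev + np.sum(ce - g, axis=1)
    fw_den = float(np.sum(env_dev**2) + np.sum(q - qbar))
    if fw_den <= 0:
        raise DegenerateDenominatorError(
            f"PEV-corrected Finlay-Wilkinson denominator is {fw_den:.3e} <= 0"
        )
    out = pd.DataFrame(
        {
            "genotype": fit.G_hat.genotype_ids,
            "lin_binns": lin,
            "env_variance": env_var,
            "ecovalence": ecov,
            "finlay_wilkinson": fw_num / fw_den,
            "average": ghat.mean(axis=1),
        }
    )
    out.attrs["estimator"] = "geno_exp_var"
    return out


def _metrics_over_draws(draws: np.ndarray, cfg: MetricConfig, fixed_reference: np.ndarray | None):
    """Vectorized metric evaluation over an (S, N, J) stack of tables."""
    S, N, J = draws.shape
    if fixed_reference is None:
        if cfg.direction == "higher_is_better":
            r = draws.argmax(axis=1)  # S x J
        else:
            r = draws.argmin(axis=1)
        best = np.take_along_axis(draws, r[:, None, :], axis=1)
    else:
        best = draws[:, fixed_reference, np.arange(J)][:, None, :]
    lin = np.sum((draws - best) ** 2, axis=2) / (2 * J)
    row_mean = draws.mean(axis=2, keepdims=True)
    env_var = np.sum((draws - row_mean) ** 2, axis=2) / (J - 1)
    col_mean = draws.mean(axis=1, keepdims=True)
    grand = draws.mean(axis=(1, 2))[:, None, None]
    ecov = np.sum((draws - row_mean - col_mean + grand) ** 2, axis=2)
    env_dev = (col_mean - grand)[:, 0, :]  # S x J
    denom = np.sum(env_dev**2, axis=1)  # (S,)
    fw = np.einsum("snj,sj->sn", draws - row_mean, env_dev) / denom[:, None]
    avg = draws.mean(axis=2)
    return {"lin_binns": lin, "env_variance": env_var, "ecovalence": ecov,
            "finlay_wilkinson": fw, "average": avg}


@dataclass
class OracleResult:
    """Monte-Carlo conditional means of the metrics with their standard errors."""

    table: pd.DataFrame
    standard_errors: pd.DataFrame
    n_draws: int


def mc_conditional_oracle(
    fit: ModelFit,
    cfg: MetricConfig | None = None,
    n_draws: int = 20000,
    seed=None,
    fixed_reference: bool = True,
) -> OracleResult:
    """Brute-force conditional expectation of every metric.

    Draws env-BV tables from ``N(G_hat, P)`` and averages the plain metric
    formulas over draws; the means converge to the closed-form ``geno_exp_var``
    values for L, S and W, and quantify the Taylor error for the
    Finlay-Wilkinson ratio.  With ``fixed_reference`` (default) Lin-Binns
    keeps the reference genotype ``r_j`` chosen from ``G_hat``, matching the
    closed form which treats ``r_j`` as fixed.
    """
    cfg = cfg or MetricConfig()
    N, J = fit.G_hat.values.shape
    if N * J > 200:
        raise ValueError("the Monte-Carlo oracle is meant for small instances (N*J <= 200)")
    P = fit.pev.dense()
    scale = max(np.trace(P) / P.shape[0], 1.0)
    for jit in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            L = np.linalg.cholesky(P + jit * scale * np.eye(P.shape[0]))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        w, V = np.linalg.eigh(P)
        if w[0] < -1e-6 * scale:
            raise np.linalg.LinAlgError("P is not positive semidefinite")
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, N * J))
    # cells are environment-major: reshape to (S, J, N) then transpose
    draws = fit.G_hat.values[None, :, :] + (z @ L.T).reshape(n_draws, J, N).transpose(0, 2, 1)
    r = metrics.reference_genotypes(fit.G_hat.values, cfg) if fixed_reference else None
    per_draw = _metrics_over_draws(draws, cfg, r)
    means = {k: v.mean(axis=0) for k, v in per_draw.items()}
    ses = {k: v.std(axis=0, ddof=1) / np.sqrt(n_draws) for k, v in per_draw.items()}
    ids = {"genotype": fit.G_hat.genotype_ids}
    table = pd.DataFrame({**ids, **means})
    table.attrs["estimator"] = "mc_oracle"
    return OracleResult(
        table=table,
        standard_errors=pd.DataFrame({**ids, **ses}),
        n_draws=n_draws,
    )
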