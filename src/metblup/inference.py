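"""Variance-component inference for the multi-environment GBLUP.

Model: ``y = X beta + Z u + e`` with ``u ~ N(0, Omega_G (x) A)`` (environment-
major ordering), ``e ~ N(0, Sigma_E)`` where ``Sigma_E`` is diagonal with one
error variance per environment, ``beta`` the fixed environment means and
``A`` a genomic relationship matrix.

``fit_components_gibbs`` is a conjugate Gibbs sampler for this model: the
across-environment genetic covariance ``Omega_G`` is unstructured with an
inverse-Wishart prior, each error variance follows a scaled inverse
chi-square, and the environment means carry a flat prior.  Unobserved
genotype-environment combinations are simply absent from the likelihood (no
data augmentation), which keeps the sampler valid under arbitrary sparseness
patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = [
    "VarianceComponents",
    "ModelSpec",
    "McmcSettings",
    "GibbsFit",
    "build_model_spec",
    "fit_components_gibbs",
    "set_known_components",
]


class IdMismatchError(KeyError):
    """A phenotype references a genotype missing from the relationship matrix."""


@dataclass
class VarianceComponents:
    """Between-environment covariance components of the MET mixed model.

    ``omega_G`` is the J x J genetic covariance across environments
    (unstructured, symmetric PSD); ``sigma2_E`` holds the J per-environment
    error variances, i.e. the diagonal of the (diagonal) ``Omega_E``.
    """

    omega_G: np.ndarray
    sigma2_E: np.ndarray
    environment_ids: list

    def __post_init__(self):
        self.omega_G = np.asarray(self.omega_G, dtype=float)
        self.sigma2_E = np.asarray(self.sigma2_E, dtype=float)
        J = len(self.environment_ids)
        if self.omega_G.shape != (J, J):
            raise ValueError("omega_G must be J x J")
        if not np.allclose(self.omega_G, self.omega_G.T, atol=1e-10):
            raise ValueError("omega_G must be symmetric")
        w = np.linalg.eigvalsh(self.omega_G)
        if w[0] < -1e-8 * max(np.trace(self.omega_G) / J, 1.0):
            raise ValueError("omega_G must be positive semidefinite")
        if self.sigma2_E.shape != (J,):
            raise ValueError("sigma2_E must have one entry per environment")
        if np.any(self.sigma2_E < 0):
            raise ValueError("error variances must be nonnegative")
        sd = np.sqrt(np.diag(self.omega_G))
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = self.omega_G / np.outer(sd, sd)
        off = rho[~np.eye(J, dtype=bool)]
        if np.any(np.abs(off[np.isfinite(off)]) > 1.0 + 1e-10):
            raise ValueError("implied genetic correlations must lie in [-1, 1]")

    @property
    def n_environments(self) -> int:
        return len(self.environment_ids)

    @property
    def omega_E(self) -> np.ndarray:
        return np.diag(self.sigma2_E)

    def genetic_correlations(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.omega_G))
        return self.omega_G / np.outer(sd, sd)


def set_known_components(omega_G, omega_E, environment_ids=None) -> VarianceComponents:
    """Wrap user-supplied (or simulation-truth) components with validation.

    ``omega_E`` may be a length-J vector of error variances or a J x J matrix,
    which must then be diagonal.
    """
    omega_G = np.asarray(omega_G, dtype=float)
    omega_E = np.asarray(omega_E, dtype=float)
    J = omega_G.shape[0]
    if omega_E.ndim == 2:
        if not np.allclose(omega_E, np.diag(np.diag(omega_E)), atol=1e-12):
            raise ValueError("omega_E must be diagonal (independent plot errors)")
        sigma2_E = np.diag(omega_E).copy()
    else:
        sigma2_E = omega_E
    if environment_ids is None:
        environment_ids = [f"env{j+1:02d}" for j in range(J)]
    return VarianceComponents(omega_G=omega_G, sigma2_E=sigma2_E, environment_ids=list(environment_ids))


@dataclass
class ModelSpec:
    """Index bookkeeping of the mixed model on the observed phenotypes.

    Observations are canonically sorted by (environment, genotype); the random
    vector ``u`` is ordered environment-major (cell ``j * N + i``) to match
    ``Omega_G (x) A``.
    """

    y: np.ndarray  # (n_obs,)
    env_idx: np.ndarray  # (n_obs,) into environment_ids
    geno_idx: np.ndarray  # (n_obs,) into genotype_ids
    A: np.ndarray  # (N, N)
    genotype_ids: list
    environment_ids: list

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_environments(self) -> int:
        return len(self.environment_ids)

    @property
    def cell_idx(self) -> np.ndarray:
        """Environment-major cell index of each observation."""
        return self.env_idx * self.n_genotypes + self.geno_idx

    def design_X(self) -> np.ndarray:
        X = np.zeros((self.n_obs, self.n_environments))
        X[np.arange(self.n_obs), self.env_idx] = 1.0
        return X


def build_model_spec(phenotypes, rel) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from long-format phenotypes and a GRM.

    ``phenotypes`` is a DataFrame with columns genotype/environment/value (an
    ``observed`` column, if present, filters the rows); duplicated
    (genotype, environment) rows are kept as replicate plots.  The genotype
    universe is that of the relationship matrix, so unphenotyped genotypes
    still receive predictions downstream.
    """
    df = phenotypes.phenotypes if hasattr(phenotypes, "phenotypes") else phenotypes
    if "observed" in df.columns:
        df = df[df["observed"]]
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError("no observed phenotypes")
    genotype_ids = list(rel.genotype_ids)
    geno_pos = {g: k for k, g in enumerate(genotype_ids)}
    unknown = set(df["genotype"]) - set(geno_pos)
    if unknown:
        raise IdMismatchError(
            f"genotypes absent from the relationship matrix: {sorted(unknown)[:5]}"
        )
    environment_ids = sorted(df["environment"].unique())
    env_pos = {e: k for k, e in enumerate(environment_ids)}
    env_idx = df["environment"].map(env_pos).to_numpy()
    geno_idx = df["genotype"].map(geno_pos).to_numpy()
    y = df["value"].to_numpy(dtype=float)
    order = np.lexsort((geno_idx, env_idx))
    return ModelSpec(
        y=y[order],
        env_idx=env_idx[order],
        geno_idx=geno_idx[order],
        A=np.asarray(rel.A, dtype=float),
        genotype_ids=genotype_ids,
        environment_ids=environment_ids,
    )


@dataclass
class McmcSettings:
    """Gibbs sampler run length and priors.

    Defaults follow the reference multitrait engine's run length (20000
    iterations, 2000 burn-in, thinning 2); :meth:`fast` gives a short profile
    for tests and desk-scale runs.  ``nu_G``/``scale_G`` parameterize the
    inverse-Wishart prior on ``Omega_G`` (``nu_G=None`` means J + 2, scale
    identity); ``nu_E``/``s2_E`` the scaled inverse chi-square prior on each
    error variance.
    """

    n_iter: int = 20000
    burn_in: int = 2000
    thin: int = 2
    seed: int | None = None
    nu_G: int | None = None
    scale_G: np.ndarray | None = None
    nu_E: float = 5.0
    s2_E: float = 1.0
    ess_warn: float = 50.0

    def __post_init__(self):
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def fast(cls, seed=None, **kw) -> "McmcSettings":
        return cls(n_iter=2000, burn_in=500, thin=2, seed=seed, **kw)


@dataclass
class GibbsFit:
    """Posterior summary of one Gibbs run."""

    components: VarianceComponents
    beta: np.ndarray
    ess: dict
    n_samples: int
    low_ess: bool


def _effective_sample_size(chain: np.ndarray) -> float:
    import arviz

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(arviz.ess(np.asarray(chain)[None, :]))


def fit_components_gibbs(spec: ModelSpec, settings: McmcSettings | None = None) -> GibbsFit:
    """Posterior means of ``Omega_G``, ``sigma2_E`` and ``beta`` by Gibbs sampling.

    Per iteration the sampler draws, in turn, each environment mean, each
    environment's genotype-effect block (conditioned on the other
    environments through the precision of ``Omega_G``), ``Omega_G`` from its
    conjugate inverse-Wishart full conditional and each error variance from a
    scaled inverse chi-square.  Chains with effective sample sizes below
    ``settings.ess_warn`` trigger a warning, never an error.
    """
    settings = settings or McmcSettings()
    rng = np.random.default_rng(settings.seed)
    N, J, n = spec.n_genotypes, spec.n_environments, spec.n_obs
    A = spec.A
    scale = max(np.trace(A) / N, 1.0)
    jitter = 0.0
    while True:
        try:
            cA = cho_factor(A + jitter * scale * np.eye(N), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12)
            if jitter > 1e-8:
                raise
    A_inv = cho_solve(cA, np.eye(N))

    nu_G = settings.nu_G if settings.nu_G is not None else J + 2
    S_G = settings.scale_G if settings.scale_G is not None else np.eye(J)

    obs_by_env = [np.flatnonzero(spec.env_idx == j) for j in range(J)]
    gidx = [spec.geno_idx[o] for o in obs_by_env]
    yj = [spec.y[o] for o in obs_by_env]
    counts = [np.bincount(g, minlength=N).astype(float) for g in gidx]
    if any(o.size == 0 for o in obs_by_env):  # pragma: no cover - builder already forbids
        raise ValueError("every environment needs at least one observation")

    beta = np.array([v.mean() for v in yj])
    U = np.zeros((N, J))
    omega = np.eye(J)
    sigma2_e = np.ones(J)

    keep = range(settings.burn_in, settings.n_iter, settings.thin)
    kept = len(keep)
    omega_draws = np.empty((kept, J, J))
    sigma2_draws = np.empty((kept, J))
    beta_draws = np.empty((kept, J))
    k = 0
    for it in range(settings.n_iter):
        # environment means (flat prior)
        for j in range(J):
            resid = yj[j] - U[gidx[j], j]
            beta[j] = rng.normal(resid.mean(), np.sqrt(sigma2_e[j] / resid.size))
        # genotype-effect blocks, one environment at a time
        K = np.linalg.inv(omega)
        for j in range(J):
            others = np.delete(np.arange(J), j)
            prior_rhs = -A_inv @ (U[:, others] @ K[others, j])
            s = np.bincount(gidx[j], weights=yj[j] - beta[j], minlength=N)
            rhs = prior_rhs + s / sigma2_e[j]
            phi = K[j, j] * A_inv + np.diag(counts[j] / sigma2_e[j])
            cP = cho_factor(phi, lower=True)
            mean = cho_solve(cP, rhs)
            z = rng.standard_normal(N)
            U[:, j] = mean + solve_triangular(cP[0], z, lower=True, trans="T")
        # unstructured genetic covariance (inverse-Wishart full conditional)
        S_post = S_G + U.T @ A_inv @ U
        S_post = (S_post + S_post.T) / 2.0
        omega = stats.invwishart.rvs(df=nu_G + N, scale=S_post, random_state=rng)
        # per-environment error variances (scaled inverse chi-square)
        for j in range(J):
            sse = np.sum((yj[j] - beta[j] - U[gidx[j], j]) ** 2)
            sigma2_e[j] = (settings.nu_E * settings.s2_E + sse) / rng.chisquare(
                settings.nu_E + yj[j].size
            )
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            omega_draws[k] = omega
            sigma2_draws[k] = sigma2_e
            beta_draws[k] = beta
            k += 1

    omega_mean = omega_draws[:k].mean(axis=0)
    omega_mean = (omega_mean + omega_mean.T) / 2.0
    components = VarianceComponents(
        omega_G=omega_mean,
        sigma2_E=sigma2_draws[:k].mean(axis=0),
        environment_ids=list(spec.environment_ids),
    )
    ess = {
        **{f"sigma2_G_{j+1}": _effective_sample_size(omega_draws[:k, j, j]) for j in range(J)},
        **{f"sigma2_E_{j+1}": _effective_sample_size(sigma2_draws[:k, j]) for j in range(J)},
    }
    low = min(ess.values()) < settings.ess_warn
    if low:
        warnings.warn(
            f"low effective sample size (min {min(ess.values()):.0f}); "
            "consider a longer chain",
            stacklevel=2,
        )
    return GibbsFit(
        components=components,
        beta=beta_draws[:k].mean(axis=0),
        ess=ess,
        n_samples=k,
        low_ess=low,
    )
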