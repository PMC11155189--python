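"""Synthetic multi-environment trial (MET) data with genomic structure.

The generator emulates a wheat-sized breeding panel: N genotypes scored at M
biallelic loci (dosages 0/1/2), a VanRaden genomic relationship matrix A, and
phenotypes from the multi-environment GBLUP generative model

    y_ij = G_ij + e_ij,     G_ij = mu_j + U_ij,
    mu_j ~ N(base_mean, sigma_mu^2)  iid,
    vec(U) ~ N(0, Omega_G (x) A),    e_ij ~ N(0, sigma2_E_j),

with unit per-environment genetic variances, a common pairwise genetic
correlation ``rho`` between environments, per-environment plot heritabilities
``h2_j = c + d_j`` (``d_j ~ U(-jitter, jitter)``) mapped to error variances
through ``sigma2_E_j = (1 - h2_j) / h2_j``, and a stated fraction of
genotype-environment combinations masked ("sparseness").  One plot is grown
per observed combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import EnvBVMatrix

__all__ = [
    "MarkerPanel",
    "RelationshipMatrix",
    "SimScenario",
    "METDataset",
    "generate_markers",
    "compute_grm",
    "simulate_envbv",
    "simulate_phenotypes",
    "simulate_met",
]


@dataclass
class MarkerPanel:
    """Biallelic dosage panel: N genotypes x M loci with entries in {0, 1, 2}."""

    genotype_ids: list
    locus_ids: list
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.genotype_ids), len(self.locus_ids)):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            raise ValueError("duplicate genotype ids")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be coded 0/1/2")

    @property
    def allele_frequencies(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


@dataclass
class RelationshipMatrix:
    """Symmetric PSD genomic (or pedigree) relationship matrix with genotype ids."""

    A: np.ndarray
    genotype_ids: list

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.genotype_ids)
        if self.A.shape != (n, n):
            raise ValueError("A must be square and match genotype_ids")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric (to within 1e-10)")
        w = np.linalg.eigvalsh(self.A)
        if w[0] < -1e-8 * max(np.trace(self.A) / n, 1.0):
            raise ValueError("A must be positive semidefinite")

    @property
    def n_genotypes(self) -> int:
        return self.A.shape[0]


@dataclass
class SimScenario:
    """Parameter bundle of one simulation condition.

    Defaults are the basic condition of the simulation study: 200 genotypes,
    10 environments, sigma_mu = 1, pairwise genetic correlation 0.5, base
    heritability 0.5 with U(-0.2, 0.2) per-environment jitter, no sparseness,
    environment means around 100.
    """

    n_genotypes: int = 200
    n_environments: int = 10
    sigma_mu: float = 1.0
    rho: float = 0.5
    h2_base: float = 0.5
    h2_jitter: float = 0.2
    sparseness: float = 0.0
    base_mean: float = 100.0
    seed: int | None = None

    def __post_init__(self):
        J = self.n_environments
        if self.n_genotypes < 2 or J < 2:
            raise ValueError("need at least 2 genotypes and 2 environments")
        if self.sigma_mu <= 0:
            raise ValueError("sigma_mu must be > 0")
        if not (-1.0 / (J - 1) < self.rho <= 1.0):
            raise ValueError(f"rho must lie in (-1/(J-1), 1] = ({-1.0/(J-1):.3f}, 1]")
        # the jitter range may touch 0 or 1 (continuous draws stay interior);
        # realized h2 is re-checked at phenotype simulation time
        if not (0 <= self.h2_base - self.h2_jitter and self.h2_base + self.h2_jitter <= 1):
            raise ValueError("h2_base +/- h2_jitter must stay inside [0, 1]")
        if not (0 <= self.sparseness < 1):
            raise ValueError("sparseness must lie in [0, 1)")

    def omega_g(self) -> np.ndarray:
        """Across-environment genetic covariance: unit variances, common rho."""
        J = self.n_environments
        return np.full((J, J), self.rho) + (1.0 - self.rho) * np.eye(J)


@dataclass
class METDataset:
    """Simulated MET phenotypes together with the simulation truth."""

    phenotypes: pd.DataFrame  # columns: genotype, environment, value, observed
    true_G: EnvBVMatrix
    true_components: "object"  # VarianceComponents; duck-typed to avoid a cycle
    scenario: SimScenario

    @property
    def observed(self) -> pd.DataFrame:
        return self.phenotypes[self.phenotypes["observed"]]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_markers(
    n_genotypes: int, n_loci: int, maf_floor: float = 0.05, seed=None
) -> MarkerPanel:
    """Draw a synthetic dosage panel with per-locus binomial(2, p) genotypes.

    Allele frequencies are drawn uniformly on (maf_floor, 1 - maf_floor) and
    loci whose *realized* minor allele frequency falls below the floor are
    redrawn, keeping the relationship matrix well conditioned.
    """
    if n_genotypes < 2 or n_loci < 1:
        raise ValueError("need n_genotypes >= 2 and n_loci >= 1")
    if not (0 < maf_floor < 0.5):
        raise ValueError("maf_floor must lie in (0, 0.5)")
    rng = _rng(seed)
    dosages = np.empty((n_genotypes, n_loci), dtype=np.int64)
    todo = np.arange(n_loci)
    for _ in range(1000):
        p = rng.uniform(maf_floor, 1 - maf_floor, size=todo.size)
        dosages[:, todo] = rng.binomial(2, p, size=(n_genotypes, todo.size))
        freq = dosages[:, todo].mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        todo = todo[maf < maf_floor]
        if todo.size == 0:
            break
    else:  # pragma: no cover - tiny panels with harsh floors only
        raise RuntimeError("could not realize the requested minor allele frequency floor")
    return MarkerPanel(
        genotype_ids=[f"g{i+1:03d}" for i in range(n_genotypes)],
        locus_ids=[f"m{m+1:04d}" for m in range(n_loci)],
        dosages=dosages,
    )


def compute_grm(panel: MarkerPanel) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix from observed frequencies.

    Dosages are centered by twice the observed allele frequency and the
    cross-product is divided by ``2 * sum_m p_m (1 - p_m)``.
    """
    p = panel.allele_frequencies
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("panel has no polymorphic locus; relationship matrix undefined")
    W = panel.dosages[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    A = (W @ W.T) / denom
    A = (A + A.T) / 2.0
    return RelationshipMatrix(A=A, genotype_ids=list(panel.genotype_ids))


def _cholesky_psd(mat: np.ndarray, max_jitter: float = 1e-8) -> np.ndarray:
    """Cholesky factor with an escalating diagonal jitter for PSD matrices."""
    scale = max(np.trace(mat) / mat.shape[0], 1.0)
    for jitter in (0.0, 1e-12, 1e-10, max_jitter):
        try:
            return np.linalg.cholesky(mat + jitter * scale * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "matrix is not positive semidefinite even after diagonal jitter"
    )


def simulate_envbv(rel: RelationshipMatrix, scenario: SimScenario, seed=None) -> EnvBVMatrix:
    """Environment-specific breeding values ``G_ij = mu_j + U_ij``.

    ``vec(U)`` is generated as the Cholesky factor of ``Omega_G (x) A`` times
    standard normal draws, realized efficiently as ``L_A Z L_Omega^T`` with
    ``Z`` an N x J standard normal matrix (environment-major vec ordering).
    """
    if rel.n_genotypes != scenario.n_genotypes:
        raise ValueError("relationship matrix size does not match the scenario")
    rng = _rng(scenario.seed if seed is None else seed)
    J = scenario.n_environments
    mu = rng.normal(scenario.base_mean, scenario.sigma_mu, size=J)
    L_omega = _cholesky_psd(scenario.omega_g())
    L_a = _cholesky_psd(rel.A)
    Z = rng.standard_normal((scenario.n_genotypes, J))
    U = L_a @ Z @ L_omega.T
    return EnvBVMatrix(
        values=mu[None, :] + U,
        genotype_ids=list(rel.genotype_ids),
        environment_ids=[f"env{j+1:02d}" for j in range(J)],
    )


def _sparseness_mask(
    N: int, J: int, n_masked: int, rng: np.random.Generator, max_resample: int = 50
) -> np.ndarray:
    """Boolean N x J mask of unobserved cells, guaranteed to leave every
    genotype and every environment with at least one observation.

    A uniform mask is drawn; if connectivity fails after a few redraws (it
    almost surely does at high sparseness) the mask is repaired by swapping
    masked cells of starved rows/columns against observed cells of
    well-covered ones, keeping the masked count exact.
    """
    if n_masked > N * J - max(N, J):
        raise ValueError("sparseness leaves too few observations to connect the design")
    for _ in range(max_resample):
        mask = np.zeros(N * J, dtype=bool)
        mask[rng.choice(N * J, size=n_masked, replace=False)] = True
        mask = mask.reshape(N, J)
        if mask.all(axis=1).sum() == 0 and mask.all(axis=0).sum() == 0:
            return mask
    # deterministic repair: free one cell in each starved row/column, re-mask
    # a cell from the best-covered rows to keep the count
    while True:
        starved_rows = np.flatnonzero(mask.all(axis=1))
        starved_cols = np.flatnonzero(mask.all(axis=0))
        if starved_rows.size == 0 and starved_cols.size == 0:
            return mask
        if starved_rows.size:
            i = starved_rows[0]
            j = rng.integers(J)
        else:
            j = starved_cols[0]
            i = rng.integers(N)
        mask[i, j] = False
        obs_per_row = (~mask).sum(axis=1)
        candidates = np.flatnonzero(obs_per_row == obs_per_row.max())
        i2 = rng.choice(candidates)
        j2 = rng.choice(np.flatnonzero(~mask[i2]))
        if (i2, j2) != (i, j) and obs_per_row[i2] > 1 and (~mask[:, j2]).sum() > 1:
            mask[i2, j2] = True


def simulate_phenotypes(G: EnvBVMatrix, scenario: SimScenario, seed=None) -> METDataset:
    """Phenotypes ``y_ij = G_ij + e_ij`` with sparseness applied.

    Per-environment heritabilities ``h2_j = h2_base + U(-jitter, jitter)`` are
    drawn afresh and mapped to error variances ``sigma2_E_j = (1-h2_j)/h2_j``
    (unit genetic variance); a uniformly random fraction ``sparseness`` of the
    N*J combinations is marked unobserved, with a connectivity guard.
    """
    from .inference import VarianceComponents  # local import: avoids a module cycle

    rng = _rng(scenario.seed + 1 if (seed is None and scenario.seed is not None) else seed)
    N, J = G.values.shape
    if (N, J) != (scenario.n_genotypes, scenario.n_environments):
        raise ValueError("env-BV matrix does not match the scenario dimensions")
    h2 = scenario.h2_base + rng.uniform(-scenario.h2_jitter, scenario.h2_jitter, size=J)
    if np.any(h2 <= 0) or np.any(h2 > 1):
        raise ValueError("per-environment heritabilities left (0, 1]")
    sigma2_e = (1.0 - h2) / h2
    y = G.values + rng.standard_normal((N, J)) * np.sqrt(sigma2_e)[None, :]

    n_masked = int(round(scenario.sparseness * N * J))
    if n_masked:
        mask = _sparseness_mask(N, J, n_masked, rng)
    else:
        mask = np.zeros((N, J), dtype=bool)

    gi, ej = np.meshgrid(np.arange(N), np.arange(J), indexing="ij")
    phen = pd.DataFrame(
        {
            "genotype": np.asarray(G.genotype_ids, dtype=object)[gi.ravel()],
            "environment": np.asarray(G.environment_ids, dtype=object)[ej.ravel()],
            "value": np.where(mask.ravel(), np.nan, y.ravel()),
            "observed": ~mask.ravel(),
        }
    )
    components = VarianceComponents(
        omega_G=scenario.omega_g(),
        sigma2_E=sigma2_e,
        environment_ids=list(G.environment_ids),
    )
    return METDataset(phenotypes=phen, true_G=G, true_components=components, scenario=scenario)


def simulate_met(
    scenario: SimScenario,
    rel: RelationshipMatrix | None = None,
    n_loci: int = 1279,
    seed=None,
) -> tuple[METDataset, RelationshipMatrix]:
    """One full MET replicate: markers -> GRM -> env-BVs -> phenotypes.

    When ``rel`` is supplied (e.g. a panel shared across replicates, the way a
    study reuses one genotyped population) only the env-BVs and phenotypes are
    redrawn.
    """
    seed = scenario.seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    r_panel, r_bv, r_phen = [np.random.default_rng(s) for s in ss.spawn(3)]
    if rel is None:
        panel = generate_markers(scenario.n_genotypes, n_loci, seed=r_panel)
        rel = compute_grm(panel)
    G = simulate_envbv(rel, scenario, seed=r_bv)
    dataset = simulate_phenotypes(G, scenario, seed=r_phen)
    return dataset, rel
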