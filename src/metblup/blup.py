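"""BLUP engine for the multi-environment GBLUP.

Given variance components this module computes, on the observed rows of the
design,

* the GLS estimate of the environment means
  ``beta_hat = (X' Sigma_Y^-1 X)^-1 X' Sigma_Y^-1 y``,
* the annihilator
  ``M = Sigma_Y^-1 - Sigma_Y^-1 X (X' Sigma_Y^-1 X)^-1 X' Sigma_Y^-1``,
* environment-specific GEBVs for *all* N x J cells (observed or not)
  ``G_hat_ij = mu_hat_j + [Sigma_G Z' M y]_ij``, and
* the prediction-error-variance structure
  ``P = Sigma_G - Sigma_G Z' Sigma_Y^-1 Z Sigma_G``

with ``Sigma_G = Omega_G (x) A`` (environment-major), ``Sigma_Y = Z Sigma_G
Z' + Sigma_E``.  ``P`` is held in the factored form
``P = Omega_G (x) A - B B' + E E'`` (``B = Sigma_G Z' L^-T``, ``L`` the
Cholesky factor of ``Sigma_Y``; ``E`` empty by default), from which single
entries and all the block averages needed by the metric BLUPs follow in
O(N J n) time without ever materializing the (N J) x (N J) matrix.

``beta`` is treated as known in ``P`` (the PEV is defined conditionally on
the fixed effects); ``add_beta_uncertainty=True`` populates ``E`` with the
fixed-effect correction for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .inference import ModelSpec, VarianceComponents
from .metrics import EnvBVMatrix

__all__ = [
    "CovarianceHandles",
    "PEVStructure",
    "ModelFit",
    "assemble_covariances",
    "estimate_beta",
    "compute_M",
    "env_gebv",
    "pev",
    "prior_pev",
    "fit_blup",
]

#: dense P is materialized on request only up to this many cells
DENSE_CELL_LIMIT = 4000


@dataclass
class CovarianceHandles:
    """Kronecker-structured covariance operators restricted to observed rows."""

    spec: ModelSpec
    vc: VarianceComponents

    def __post_init__(self):
        if self.vc.n_environments != self.spec.n_environments:
            raise ValueError("component dimension does not match the model spec")

    def sigma_y(self) -> np.ndarray:
        """Dense n x n covariance of the observed phenotypes."""
        s = self.spec
        omega, sig2 = self.vc.omega_G, self.vc.sigma2_E
        out = omega[np.ix_(s.env_idx, s.env_idx)] * s.A[np.ix_(s.geno_idx, s.geno_idx)]
        out[np.diag_indices_from(out)] += sig2[s.env_idx]
        return out

    def sigma_g_zt(self) -> np.ndarray:
        """Dense (N J) x n block ``Sigma_G Z'``: cross-covariance of all cells
        with the observed rows (environment-major cell order)."""
        s = self.spec
        N, J = s.n_genotypes, s.n_environments
        omega_cols = self.vc.omega_G[:, s.env_idx]  # J x n
        a_cols = s.A[:, s.geno_idx]  # N x n
        return (omega_cols[:, None, :] * a_cols[None, :, :]).reshape(N * J, s.n_obs)

    def sigma_g_dense(self) -> np.ndarray:
        """Dense ``Omega_G (x) A`` for small problems (tests, oracles)."""
        return np.kron(self.vc.omega_G, self.spec.A)


def assemble_covariances(spec: ModelSpec, vc: VarianceComponents) -> CovarianceHandles:
    return CovarianceHandles(spec=spec, vc=vc)


def _chol_sigma_y(handles: CovarianceHandles, max_jitter: float = 1e-8):
    sy = handles.sigma_y()
    scale = max(np.trace(sy) / sy.shape[0], 1.0)
    jitter = 0.0
    while True:
        try:
            return cho_factor(sy + jitter * scale * np.eye(sy.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12)
            if jitter > max_jitter:
                raise


def _solve_gls(spec, vc, cy=None):
    cy = cy if cy is not None else _chol_sigma_y(assemble_covariances(spec, vc))
    X = spec.design_X()
    siX = cho_solve(cy, X)
    xtsx = X.T @ siX
    try:
        beta = np.linalg.solve(xtsx, siX.T @ spec.y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("X' Sigma_Y^-1 X is singular") from err
    return beta, cy, siX, xtsx


def estimate_beta(spec: ModelSpec, vc: VarianceComponents) -> np.ndarray:
    """GLS environment means (the BLUE of beta)."""
    return _solve_gls(spec, vc)[0]


class _MOperator:
    """The GLS annihilator ``M``, applied through Cholesky solves.

    Satisfies ``M X = 0`` and ``M (y + X c) = M y`` for any ``c``.
    """

    def __init__(self, spec, vc):
        self.spec = spec
        _, self.cy, self.siX, self.xtsx = _solve_gls(spec, vc)

    def apply(self, v: np.ndarray) -> np.ndarray:
        siv = cho_solve(self.cy, v)
        return siv - self.siX @ np.linalg.solve(self.xtsx, self.siX.T @ v)

    def dense(self) -> np.ndarray:
        return self.apply(np.eye(self.spec.n_obs))


def compute_M(spec: ModelSpec, vc: VarianceComponents) -> _MOperator:
    return _MOperator(spec, vc)


@dataclass
class PEVStructure:
    """Conditional covariance of the env-BVs given phenotypes, factored as
    ``P = Omega_G (x) A - B B' + E E'`` with cells ordered environment-major
    (cell ``j * N + i``).  ``E`` is empty unless the fixed-effect correction
    was requested."""

    omega_G: np.ndarray
    A: np.ndarray
    B: np.ndarray  # (N J) x n_obs; empty second axis when nothing is observed
    E: np.ndarray | None = None

    def __post_init__(self):
        if self.E is None:
            self.E = np.zeros((self.B.shape[0], 0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape[0], self.omega_G.shape[0]

    @cached_property
    def _B3(self) -> np.ndarray:
        N, J = self.shape
        return self.B.reshape(J, N, -1)

    @cached_property
    def _E3(self) -> np.ndarray:
        N, J = self.shape
        return self.E.reshape(J, N, -1)

    def entry(self, i: int, j: int, i2: int, j2: int) -> float:
        """Single element ``P_{(i,j),(i2,j2)}``."""
        return float(
            self.omega_G[j, j2] * self.A[i, i2]
            - self._B3[j, i] @ self._B3[j2, i2]
            + self._E3[j, i] @ self._E3[j2, i2]
        )

    def dense(self) -> np.ndarray:
        """Materialized P; refused beyond :data:`DENSE_CELL_LIMIT` cells."""
        N, J = self.shape
        if N * J > DENSE_CELL_LIMIT:
            raise MemoryError(
                f"dense P with {N*J} cells exceeds the materialization threshold; "
                "use the contraction methods instead"
            )
        return np.kron(self.omega_G, self.A) - self.B @ self.B.T + self.E @ self.E.T

    # -- contraction families used by the metric BLUPs ----------------------

    def _lowrank(self, contraction):
        """Apply a contraction to the -BB' + EE' part."""
        return contraction(self._B3) - contraction(self._E3)

    @cached_property
    def diagonal(self) -> np.ndarray:
        """``P_{(i,j),(i,j)}`` as an N x J array."""
        d = np.diag(self.A)[:, None] * np.diag(self.omega_G)[None, :]
        return d - self._lowrank(lambda F: (F**2).sum(axis=2).T)

    @cached_property
    def within_genotype_env_mean(self) -> np.ndarray:
        """``(1/J) sum_j' P_{(i,j),(i,j')}`` as N x J."""
        N, J = self.shape
        prior = np.diag(self.A)[:, None] * self.omega_G.mean(axis=1)[None, :]

        def contraction(F):
            genotype_sum = F.sum(axis=0)  # N x r
            return np.einsum("jir,ir->ij", F, genotype_sum) / J

        return prior - self._lowrank(contraction)

    @cached_property
    def within_env_genotype_mean(self) -> np.ndarray:
        """``(1/N) sum_i' P_{(i,j),(i',j)}`` as N x J."""
        N, J = self.shape
        prior = self.A.mean(axis=1)[:, None] * np.diag(self.omega_G)[None, :]

        def contraction(F):
            env_sum = F.sum(axis=1)  # J x r
            return np.einsum("jir,jr->ij", F, env_sum) / N

        return prior - self._lowrank(contraction)

    @cached_property
    def grand_row_mean(self) -> np.ndarray:
        """``(1/(J N)) sum_j' sum_i' P_{(i,j),(i',j')}`` as N x J."""
        N, J = self.shape
        prior = self.A.mean(axis=1)[:, None] * self.omega_G.mean(axis=1)[None, :]

        def contraction(F):
            total = F.sum(axis=(0, 1))  # (r,)
            return ((F @ total) / (J * N)).T

        return prior - self._lowrank(contraction)

    @cached_property
    def env_block_double_mean(self) -> np.ndarray:
        """``q2[j, j'] = (1/N^2) sum_{i', i''} P_{(i',j),(i'',j')}`` (J x J)."""
        N, J = self.shape

        def contraction(F):
            env_sum = F.sum(axis=1)  # J x r
            return (env_sum @ env_sum.T) / N**2

        return self.omega_G * self.A.mean() - self._lowrank(contraction)

    def cross_with_reference(self, reference: np.ndarray) -> np.ndarray:
        """``P_{(i,j),(r_j,j)}`` for a per-environment reference genotype
        ``r_j``, as N x J."""
        N, J = self.shape
        reference = np.asarray(reference)
        prior = self.A[:, reference] * np.diag(self.omega_G)[None, :]

        def contraction(F):
            return np.einsum("jir,jr->ij", F, F[np.arange(J), reference])

        return prior - self._lowrank(contraction)


@dataclass
class ModelFit:
    """Fitted environment means, env-GEBVs and PEV structure of one model."""

    beta_hat: np.ndarray
    G_hat: EnvBVMatrix
    pev: PEVStructure
    components: VarianceComponents
    spec: ModelSpec


def fit_blup(
    spec: ModelSpec, vc: VarianceComponents, add_beta_uncertainty: bool = False
) -> ModelFit:
    """One shot: BLUE of beta, env-GEBVs for every cell, and the PEV factors."""
    handles = assemble_covariances(spec, vc)
    cy = _chol_sigma_y(handles)
    beta, cy, siX, xtsx = _solve_gls(spec, vc, cy=cy)
    sgzt = handles.sigma_g_zt()
    my = cho_solve(cy, spec.y - spec.design_X() @ beta)
    N, J = spec.n_genotypes, spec.n_environments
    cell_env = np.repeat(np.arange(J), N)
    ghat_cells = beta[cell_env] + sgzt @ my
    G_hat = EnvBVMatrix(
        values=ghat_cells.reshape(J, N).T,
        genotype_ids=list(spec.genotype_ids),
        environment_ids=list(spec.environment_ids),
    )
    B = solve_triangular(cy[0], sgzt.T, lower=True).T
    E = None
    if add_beta_uncertainty:
        # Var contribution of estimating beta: (Xg - Sigma_G Z' Sy^-1 X) C (.)'
        # with C = (X' Sy^-1 X)^-1 and Xg the cell-level environment design.
        Xg = np.zeros((N * J, J))
        Xg[np.arange(N * J), cell_env] = 1.0
        D = Xg - sgzt @ siX
        C = np.linalg.inv(xtsx)
        E = D @ np.linalg.cholesky((C + C.T) / 2.0)
    return ModelFit(
        beta_hat=beta,
        G_hat=G_hat,
        pev=PEVStructure(vc.omega_G, spec.A, B, E),
        components=vc,
        spec=spec,
    )


def env_gebv(spec: ModelSpec, vc: VarianceComponents) -> ModelFit:
    """Alias of :func:`fit_blup`, named for its headline output."""
    return fit_blup(spec, vc)


def pev(
    spec: ModelSpec, vc: VarianceComponents, add_beta_uncertainty: bool = False
) -> PEVStructure:
    """Prediction-error-variance structure ``P`` of all N x J env-BVs."""
    return fit_blup(spec, vc, add_beta_uncertainty=add_beta_uncertainty).pev


def prior_pev(rel_or_spec, vc: VarianceComponents) -> PEVStructure:
    """PEV with no observations: ``P = Sigma_G`` entrywise."""
    A = np.asarray(rel_or_spec.A, dtype=float)
    return PEVStructure(vc.omega_G, A, np.zeros((A.shape[0] * vc.n_environments, 0)))
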