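"""Superiority and stability metrics computed from environment-specific values.

Given a complete N x J table ``G`` of environment-specific breeding values
(or any environment-specific genotype values), this module computes the five
classical genotype-by-environment (GE) metrics:

* Lin-Binns superiority measure ``L_i``: mean squared distance to the
  best-performing genotype of each environment (low = superior).
* Environmental Variance ``S_i``: variance of a genotype's performance across
  environments (static stability; low = stable).
* Ecovalence ``W_i``: a genotype's contribution to the GE interaction sum of
  squares of the two-way ANOVA decomposition (dynamic stability; low = stable).
* Finlay-Wilkinson regression coefficient ``B_i``: slope of a genotype's
  values regressed on the environment means (static around 0, dynamic
  around 1).
* Average performance: the plain row mean.

Dot-subscript conventions follow the field's usage: ``G_i.`` is the average of
genotype i over environments, ``G_.j`` the average of environment j over
genotypes, ``G_..`` the grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnvBVMatrix",
    "MetricConfig",
    "METRIC_NAMES",
    "lin_binns",
    "environmental_variance",
    "ecovalence",
    "finlay_wilkinson",
    "average_performance",
    "metric_table",
]

#: canonical metric column order used across the package
METRIC_NAMES = ("lin_binns", "env_variance", "ecovalence", "finlay_wilkinson", "average")


class IncompleteInputError(ValueError):
    """Raised when a metric is requested on a table with missing entries."""


class DegenerateRegressorError(ValueError):
    """Raised when the Finlay-Wilkinson regressor (environment means) is constant."""


@dataclass
class EnvBVMatrix:
    """N x J table of environment-specific values for N genotypes in J environments."""

    values: np.ndarray
    genotype_ids: list
    environment_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (genotypes x environments) array")
        n, j = self.values.shape
        if len(self.genotype_ids) != n or len(self.environment_ids) != j:
            raise ValueError("id lists do not match the shape of `values`")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("duplicate genotype ids")
        if n < 2 or j < 2:
            raise ValueError("need at least 2 genotypes and 2 environments")
        if not np.all(np.isfinite(self.values)):
            raise IncompleteInputError("values contain missing/non-finite entries")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_environments(self) -> int:
        return self.values.shape[1]


@dataclass
class MetricConfig:
    """Options shared by the metric estimators.

    direction
        ``"higher_is_better"`` (yield-like traits, default) or
        ``"lower_is_better"``; controls which genotype is the per-environment
        reference ``r_j`` of Lin-Binns and the tail selected in coincidence
        studies.
    """

    direction: str = "higher_is_better"

    def __post_init__(self):
        if self.direction not in ("higher_is_better", "lower_is_better"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _as_values(G) -> np.ndarray:
    values = G.values if isinstance(G, EnvBVMatrix) else np.asarray(G, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D genotypes x environments table")
    if not np.all(np.isfinite(values)):
        raise IncompleteInputError("metrics require a complete table without missing entries")
    return values


def reference_genotypes(values: np.ndarray, cfg: MetricConfig | None = None) -> np.ndarray:
    """Index of the best genotype ``r_j`` per environment, ties to lowest index."""
    cfg = cfg or MetricConfig()
    # np.argmax/argmin return the first occurrence, i.e. the lowest index on ties
    if cfg.direction == "higher_is_better":
        return np.argmax(values, axis=0)
    return np.argmin(values, axis=0)


def lin_binns(G, cfg: MetricConfig | None = None) -> np.ndarray:
    """Lin-Binns superiority measure ``L_i = (1/2J) sum_j (G_ij - G_{r_j j})^2``."""
    values = _as_values(G)
    J = values.shape[1]
    r = reference_genotypes(values, cfg)
    best = values[r, np.arange(J)]
    return np.sum((values - best) ** 2, axis=1) / (2 * J)


def environmental_variance(G) -> np.ndarray:
    """Environmental Variance ``S_i``: sample variance of each row (ddof=1)."""
    values = _as_values(G)
    if values.shape[1] < 2:
        raise ValueError("Environmental Variance needs at least 2 environments")
    return np.var(values, axis=1, ddof=1)


def ecovalence(G) -> np.ndarray:
    """Ecovalence ``W_i``: row sums of squared double-centered deviations."""
    values = _as_values(G)
    centered = (
        values
        - values.mean(axis=1, keepdims=True)
        - values.mean(axis=0, keepdims=True)
        + values.mean()
    )
    return np.sum(centered**2, axis=1)


def finlay_wilkinson(G) -> np.ndarray:
    """Finlay-Wilkinson slope of each genotype's values on the environment means.

    ``B_i = sum_j (G_ij - G_i.)(G_.j - G_..) / sum_j (G_.j - G_..)^2``; the
    mean of ``B_i`` over genotypes is exactly 1.
    """
    values = _as_values(G)
    env_dev = values.mean(axis=0) - values.mean()
    denom = np.sum(env_dev**2)
    if denom <= np.finfo(float).tiny * max(1.0, np.abs(values).max()) ** 2:
        raise DegenerateRegressorError(
            "environment means are (numerically) constant; the Finlay-Wilkinson "
            "slope is undefined"
        )
    row_dev = values - values.mean(axis=1, keepdims=True)
    return row_dev @ env_dev / denom


def average_performance(G) -> np.ndarray:
    """Average performance ``G_i.``: the row mean."""
    return _as_values(G).mean(axis=1)


def metric_table(G, cfg: MetricConfig | None = None, label: str = "true") -> pd.DataFrame:
    """All five metrics of a complete table as a tidy per-genotype DataFrame.

    The returned frame has columns ``genotype`` plus :data:`METRIC_NAMES` and
    carries the estimator label in ``attrs["estimator"]``.
    """
    cfg = cfg or MetricConfig()
    values = _as_values(G)
    ids = G.genotype_ids if isinstance(G, EnvBVMatrix) else list(range(values.shape[0]))
    out = pd.DataFrame(
        {
            "genotype": ids,
            "lin_binns": lin_binns(values, cfg),
            "env_variance": environmental_variance(values),
            "ecovalence": ecovalence(values),
            "finlay_wilkinson": finlay_wilkinson(values),
            "average": average_performance(values),
        }
    )
    out.attrs["estimator"] = label
    return out
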