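"""Estimator-performance machinery.

Precision criteria
    * Pearson correlation between metric estimates and reference values.
    * Scaled RMSE: root-mean-squared error divided by the standard deviation
      of the reference values, making magnitudes comparable across metrics.
    * Selection coincidence: percent overlap between the k genotypes selected
      on the estimates and on the reference values at a given selection
      intensity (k = round(intensity * N)); defined for Lin-Binns,
      Environmental Variance, Ecovalence and Average (a low value is treated
      as desirable for all four), not for Finlay-Wilkinson.

Workflows
    * :func:`cv1_run` — CV1 cross-validation: all phenotypes of the test
      genotypes are discarded before fitting, and criteria are computed on
      the test set only (genomic estimators only, since the phenotype-only
      estimator carries no information across genotypes).
    * :func:`run_scenario_grid` — full-data estimation replicated over
      simulation scenarios, producing a tidy criterion table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from .blup import ModelFit, fit_blup
from .inference import McmcSettings, VarianceComponents, build_model_spec, fit_components_gibbs
from .metrics import MetricConfig, metric_table
from .simdata import METDataset, RelationshipMatrix, SimScenario, compute_grm, generate_markers, simulate_met

__all__ = [
    "CVPlan",
    "selection_coincidence",
    "scaled_rmse",
    "estimate_all",
    "cv1_run",
    "run_scenario_grid",
    "COINCIDENCE_METRICS",
]

log = logging.getLogger(__name__)

#: metrics for which tail selection is meaningful (not Finlay-Wilkinson)
COINCIDENCE_METRICS = ("lin_binns", "env_variance", "ecovalence", "average")


def selection_coincidence(
    estimates, truth, intensity: float, direction: str = "lower"
) -> float:
    """Percent overlap of the bottom-k (or top-k) genotype sets.

    ``k = round(intensity * N)``; ties are broken by (lowest) genotype index
    through a stable argsort.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.shape != truth.shape or estimates.ndim != 1:
        raise ValueError("estimates and truth must be matching 1-D vectors")
    n = estimates.size
    k = int(round(intensity * n))
    if k < 1:
        raise ValueError("intensity * N must be at least 1")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    sign = 1.0 if direction == "lower" else -1.0
    sel_est = set(np.argsort(sign * estimates, kind="stable")[:k])
    sel_true = set(np.argsort(sign * truth, kind="stable")[:k])
    return 100.0 * len(sel_est & sel_true) / k


def scaled_rmse(estimates, truth) -> float:
    """RMSE between estimates and reference, scaled by sd(reference)."""
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if truth.size < 2:
        raise ValueError("need at least two genotypes")
    sd = truth.std(ddof=1)
    if sd == 0:
        raise ValueError("reference values are constant; scaled RMSE undefined")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)) / sd)


def _correlation(estimates, truth) -> float:
    """Pearson correlation; NaN when either side is (numerically) constant."""
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    tol = 1e-12
    if (
        estimates.std() <= tol * max(1.0, np.abs(estimates.mean()))
        or truth.std() <= tol * max(1.0, np.abs(truth.mean()))
    ):
        return float("nan")
    return float(np.corrcoef(estimates, truth)[0, 1])


def _resolve_components(components, dataset, spec, settings, seed):
    if isinstance(components, VarianceComponents):
        return components
    if components == "true":
        if dataset is None or not isinstance(dataset, METDataset):
            raise ValueError("components='true' needs a simulated METDataset")
        return dataset.true_components
    if components == "mcmc":
        settings = settings or McmcSettings.fast()
        if seed is not None:
            settings = McmcSettings(
                n_iter=settings.n_iter, burn_in=settings.burn_in, thin=settings.thin,
                seed=seed, nu_G=settings.nu_G, scale_G=settings.scale_G,
                nu_E=settings.nu_E, s2_E=settings.s2_E, ess_warn=settings.ess_warn,
            )
        return fit_components_gibbs(spec, settings).components
    raise ValueError(f"unknown components policy {components!r}")


def estimate_all(
    phenotypes,
    rel: RelationshipMatrix,
    cfg: MetricConfig | None = None,
    which=est.ESTIMATOR_LABELS,
    components="mcmc",
    dataset: METDataset | None = None,
    settings: McmcSettings | None = None,
    seed=None,
) -> dict:
    """MetricTables for the requested estimator families on one dataset.

    The genomic families share a single model fit.  Returns a dict label ->
    DataFrame; the fitted :class:`ModelFit` is stashed under ``"_fit"`` when a
    genomic estimator was requested.
    """
    cfg = cfg or MetricConfig()
    out: dict = {}
    df = phenotypes.phenotypes if hasattr(phenotypes, "phenotypes") else phenotypes
    if "no_geno" in which:
        out["no_geno"] = est.no_geno_estimates(
            df, cfg, genotype_ids=list(rel.genotype_ids)
        )
    genomic = [w for w in which if w != "no_geno"]
    if genomic:
        spec = build_model_spec(df, rel)
        vc = _resolve_components(components, dataset, spec, settings, seed)
        fit = fit_blup(spec, vc)
        out["_fit"] = fit
        if "geno_exp" in genomic:
            out["geno_exp"] = est.geno_exp_estimates(fit, cfg)
        if "geno_exp_var" in genomic:
            out["geno_exp_var"] = est.geno_exp_var_estimates(fit, cfg)
    return out


@dataclass
class CVPlan:
    """CV1 plan: training fraction of genotypes, repeats, master seed."""

    train_fraction: float = 0.5
    n_repeats: int = 50
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must lie in (0, 1]")
        if self.train_fraction not in (0.25, 0.5, 0.75, 1.0):
            warnings.warn(
                f"train_fraction {self.train_fraction} is outside the standard "
                "grid {0.25, 0.5, 0.75}",
                stacklevel=2,
            )


def _sample_training_set(df, genotype_ids, fraction, rng, max_tries=100):
    n = len(genotype_ids)
    k = int(round(fraction * n))
    envs = df["environment"].unique()
    for _ in range(max_tries):
        train = rng.choice(n, size=k, replace=False)
        train_ids = {genotype_ids[i] for i in train}
        kept = df[df["genotype"].isin(train_ids)]
        if set(kept["environment"].unique()) == set(envs):
            return np.sort(train)
        log.info("resampled CV training set: an environment lost all observations")
    raise RuntimeError("could not sample a training set covering every environment")


def cv1_run(
    dataset,
    rel: RelationshipMatrix,
    plan: CVPlan,
    which=("geno_exp", "geno_exp_var"),
    components="true",
    settings: McmcSettings | None = None,
    cfg: MetricConfig | None = None,
) -> pd.DataFrame:
    """CV1: predict GE metrics of genotypes with no phenotypes anywhere.

    Per repeat, a training fraction of genotypes is sampled, every phenotype
    of the remaining (test) genotypes is discarded, the model is fitted on
    the training data (with the relationship matrix carrying information to
    the test genotypes), and metric estimates of the test genotypes are
    scored against the reference: true metrics (simulated data) or the
    phenotype-based estimates (empirical mode).  Returns a tidy frame with
    one row per repeat x estimator x metric x criterion.
    """
    cfg = cfg or MetricConfig()
    if any(w == "no_geno" for w in which):
        raise ValueError("CV1 applies to genomic estimators only")
    df = dataset.phenotypes if isinstance(dataset, METDataset) else dataset
    if isinstance(dataset, METDataset):
        reference = metric_table(dataset.true_G, cfg, label="true")
    else:
        reference = est.no_geno_estimates(df, cfg, genotype_ids=list(rel.genotype_ids))
    reference = reference.set_index("genotype")
    genotype_ids = list(rel.genotype_ids)
    observed = df[df["observed"]] if "observed" in df.columns else df.dropna(subset=["value"])

    ss = np.random.SeedSequence(plan.seed)
    rows = []
    for repeat, child in enumerate(ss.spawn(plan.n_repeats)):
        rng = np.random.default_rng(child)
        if plan.train_fraction >= 1.0:
            train = np.arange(len(genotype_ids))
        else:
            train = _sample_training_set(observed, genotype_ids, plan.train_fraction, rng)
        train_ids = {genotype_ids[i] for i in train}
        test_ids = [g for g in genotype_ids if g not in train_ids] or genotype_ids
        kept = observed[observed["genotype"].isin(train_ids)]
        tables = estimate_all(
            kept, rel, cfg, which=which,
            components=components, dataset=dataset if isinstance(dataset, METDataset) else None,
            settings=settings, seed=rng.integers(2**31) if components == "mcmc" else None,
        )
        for label in which:
            table = tables[label].set_index("genotype").loc[test_ids]
            ref = reference.loc[test_ids]
            for metric in table.columns:
                rows.append(
                    {
                        "repeat": repeat,
                        "train_fraction": plan.train_fraction,
                        "estimator": label,
                        "metric": metric,
                        "correlation": _correlation(table[metric], ref[metric]),
                        "scaled_rmse": scaled_rmse(table[metric], ref[metric])
                        if ref[metric].std(ddof=1) > 0
                        else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def run_scenario_grid(
    scenarios,
    n_replicates: int,
    seed=None,
    rel: RelationshipMatrix | None = None,
    which=est.ESTIMATOR_LABELS,
    components="true",
    settings: McmcSettings | None = None,
    intensities=(0.05, 0.10, 0.15, 0.20),
    cfg: MetricConfig | None = None,
    n_loci: int = 1279,
) -> pd.DataFrame:
    """Full-data estimator benchmark over simulation scenarios.

    One marker panel / relationship matrix is generated from the master seed
    and shared by every scenario and replicate (the way a study reuses a
    single genotyped population); env-BVs and phenotypes are redrawn per
    replicate.  Returns a tidy frame keyed by scenario x replicate x
    estimator x metric x criterion (correlation, scaled_rmse and, for the
    tail-selectable metrics, coincidence at each intensity).
    """
    cfg = cfg or MetricConfig()
    if isinstance(scenarios, SimScenario):
        scenarios = [scenarios]
    ss = np.random.SeedSequence(seed)
    panel_ss, *rep_ss = ss.spawn(1 + n_replicates * len(scenarios))
    if rel is None:
        n_genotypes = scenarios[0].n_genotypes
        if any(s.n_genotypes != n_genotypes for s in scenarios):
            raise ValueError("scenarios sharing one panel must agree on n_genotypes")
        panel = generate_markers(n_genotypes, n_loci, seed=np.random.default_rng(panel_ss))
        rel = compute_grm(panel)

    rows = []
    failures = 0
    for s_idx, scenario in enumerate(scenarios):
        label = scenario_label(scenario)
        for r_idx in range(n_replicates):
            child = rep_ss[s_idx * n_replicates + r_idx]
            try:
                dataset, _ = simulate_met(scenario, rel=rel, seed=child)
                truth = metric_table(dataset.true_G, cfg, label="true").set_index("genotype")
                tables = estimate_all(
                    dataset, rel, cfg, which=which, components=components,
                    dataset=dataset, settings=settings,
                    seed=int(np.random.default_rng(child).integers(2**31))
                    if components == "mcmc" else None,
                )
            except Exception:  # pragma: no cover - per-replicate guard
                failures += 1
                log.exception("replicate %d of scenario %s failed; skipped", r_idx, label)
                continue
            for est_label in which:
                table = tables[est_label].set_index("genotype").loc[truth.index]
                for metric in table.columns:
                    base = {
                        "scenario": label,
                        "replicate": r_idx,
                        "estimator": est_label,
                        "metric": metric,
                    }
                    rows.append(
                        {**base, "criterion": "correlation",
                         "value": _correlation(table[metric], truth[metric])}
                    )
                    rows.append(
                        {**base, "criterion": "scaled_rmse",
                         "value": scaled_rmse(table[metric], truth[metric])}
                    )
                    if metric in COINCIDENCE_METRICS:
                        for intensity in intensities:
                            if round(intensity * scenario.n_genotypes) < 1:
                                continue  # selection set would be empty
                            rows.append(
                                {**base,
                                 "criterion": f"coincidence_{int(round(100 * intensity))}",
                                 "value": selection_coincidence(
                                     table[metric], truth[metric], intensity, "lower"
                                 )}
                            )
    if failures:
        log.warning("%d replicates failed and were skipped", failures)
    return pd.DataFrame(rows)


def scenario_label(s: SimScenario) -> str:
    return (
        f"N{s.n_genotypes}_J{s.n_environments}_mu{s.sigma_mu:g}_rho{s.rho:g}"
        f"_h2{s.h2_base:g}_sp{int(round(100 * s.sparseness))}"
    )
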