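"""Infer environment means and variance components by Gibbs sampling.

Fits the multi-environment GBLUP (unstructured genetic covariance across
environments, diagonal error covariance) on a simulated trial with two plots
per combination and compares posterior means to the simulation truth.
"""

import warnings

import numpy as np
import pandas as pd

import metblup as mb
from metblup.inference import McmcSettings, build_model_spec, fit_components_gibbs

scenario = mb.SimScenario(n_genotypes=150, n_environments=4, seed=8)
dataset, rel = mb.simulate_met(scenario, n_loci=400)

# a second plot per combination pins down the error variances
rng = np.random.default_rng(9)
extra = dataset.phenotypes.copy()
extra["value"] = (
    dataset.true_G.values
    + rng.standard_normal((150, 4)) * np.sqrt(dataset.true_components.sigma2_E)
).ravel()
spec = build_model_spec(pd.concat([dataset.phenotypes, extra]), rel)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = fit_components_gibbs(spec, McmcSettings.fast(seed=2))

rho = fit.components.genetic_correlations()
print("posterior-mean genetic variances:", np.diag(fit.components.omega_G).round(2), "(truth 1)")
print("posterior-mean genetic correlations (off-diag mean):",
      round(float(rho[~np.eye(4, dtype=bool)].mean()), 3), "(truth 0.5)")
print("posterior-mean error variances:", fit.components.sigma2_E.round(2))
print("simulated error variances:     ", dataset.true_components.sigma2_E.round(2))
print("min effective sample size:", round(min(fit.ess.values())))
print("\nThe chain uses the short profile (2000 iterations); the default "
      "profile is 20000/2000/2.")
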