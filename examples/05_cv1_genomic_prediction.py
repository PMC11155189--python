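"""Predict GE metrics of genotypes never observed in any environment (CV1).

All phenotypes of the held-out genotypes are discarded; the genomic
relationship matrix carries information from their relatives.  Predictive
ability is the correlation between predicted and true metrics on the test
set, averaged over repeated splits.
"""

import metblup as mb
from metblup.evaluation import CVPlan, cv1_run

scenario = mb.SimScenario(seed=12)  # basic: N=200, J=10, complete
dataset, rel = mb.simulate_met(scenario)

for fraction in (0.25, 0.5, 0.75):
    res = cv1_run(
        dataset, rel, CVPlan(train_fraction=fraction, n_repeats=10, seed=3),
        components="true",
    )
    med = (
        res[res.estimator == "geno_exp_var"]
        .groupby("metric")["correlation"]
        .median()
        .round(2)
    )
    print(f"train fraction {fraction:.0%}: " + ", ".join(f"{m}={v}" for m, v in med.items()))
print(
    "\nPredictive ability rises with training set size; with an essentially "
    "unrelated synthetic panel the absolute levels stay modest, and the "
    "superiority metrics (average, lin_binns) lead the stability metrics."
)
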