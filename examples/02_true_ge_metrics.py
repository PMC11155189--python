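"""Compute the five superiority/stability metrics from a complete table.

Uses simulated environment-specific breeding values as if they were known;
in practice the same functions run on any genotypes x environments table of
adjusted means.
"""

import metblup as mb
from metblup.metrics import metric_table

scenario = mb.SimScenario(n_genotypes=8, n_environments=5, seed=11)
dataset, _ = mb.simulate_met(scenario, n_loci=200)

table = metric_table(dataset.true_G, label="true")
print(table.round(2).to_string(index=False))
print(
    "\nlin_binns: mean squared gap to the best genotype per environment "
    "(low = superior). env_variance: spread of a genotype across environments "
    "(low = statically stable). ecovalence: contribution to the GxE interaction "
    "sum of squares (low = dynamically stable). finlay_wilkinson: slope on the "
    "environment means (1 = tracks the average environment). average: plain "
    "mean performance."
)
print(f"\nmean Finlay-Wilkinson slope: {table['finlay_wilkinson'].mean():.6f} (exactly 1)")
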