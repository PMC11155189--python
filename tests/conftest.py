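import numpy as np
import pytest

import metblup as mb
from metblup.evaluation import run_scenario_grid


@pytest.fixture(scope="session")
def table2_results():
    """50 replicates of the basic scenario with 25% sparseness.

    Variance components are reused from the simulation truth (the fast
    estimation mode); one synthetic 200 x 1279 panel is shared by all
    replicates.
    """
    scenario = mb.SimScenario(sparseness=0.25)
    return run_scenario_grid(scenario, n_replicates=50, seed=1, components="true")


@pytest.fixture(scope="session")
def small_fit():
    """A 5 x 3 instance with one masked fraction and known components."""
    scenario = mb.SimScenario(
        n_genotypes=5, n_environments=3, sparseness=0.2, seed=3
    )
    dataset, rel = mb.simulate_met(scenario, n_loci=60)
    spec = mb.build_model_spec(dataset, rel)
    return mb.fit_blup(spec, dataset.true_components), dataset, rel
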