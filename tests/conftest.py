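import numpy as np
import pytest

from uafit import (
    SimulationCondition,
    run_condition,
    simple_structure,
    table1_population,
)

#: master seed of the test suite's Monte-Carlo runs
SEED = 20260919


@pytest.fixture(scope="session")
def ref_pop():
    """Reference study condition: q*=1, p=8, misfit type I, targets (.05, .95)."""
    return table1_population(1, 8, "I", 0.95)


@pytest.fixture(scope="session")
def ref_spec():
    return simple_structure(8, 1)


@pytest.fixture(scope="session")
def ref_run(ref_pop):
    """300 paired replications (n=1000) of the reference condition.

    Shared by the acceptance tests; covers ML and ULSMV on the metric data
    and ULSMV on the paired mean-split dichotomous data.
    """
    cond = SimulationCondition(pop=ref_pop, n=1000, reps=300, seed=SEED)
    return run_condition(cond)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
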