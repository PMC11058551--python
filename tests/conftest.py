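import numpy as np
import pytest
from dataclasses import replace

from survpower import Scenario, example_scenario, generate_cohort, run_replications


@pytest.fixture(scope="session")
def scenario() -> Scenario:
    """The packaged worked-example scenario (n=5000, alpha=0.05)."""
    return example_scenario()


@pytest.fixture(scope="session")
def exponential_scenario(scenario) -> Scenario:
    """Same design with constant hazard (shape 1)."""
    return replace(scenario, outcome=replace(scenario.outcome, gamma=1.0))


@pytest.fixture(scope="session")
def cohort(scenario):
    """One seeded cohort from the example scenario."""
    return generate_cohort(scenario, np.random.default_rng(20230413))


@pytest.fixture(scope="session")
def alt_replications(scenario):
    """Shared alternative-mode replication run, reused across tests."""
    return run_replications(scenario, 500, "alternative", master_seed=97)
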