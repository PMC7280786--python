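import numpy as np
import pytest

from brainage import SimulationConfig, generate_cohort, small_schema


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down cohort (103 phenotypes, 800 subjects) shared across tests."""
    cfg = SimulationConfig(n_subjects=800, seed=101, schema=small_schema(10))
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
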