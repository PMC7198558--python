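import numpy as np
import pytest

from tgctk.cohort import CohortConfig, generate_cohort, synthetic_reference_signatures
from tgctk.genome import default_genome


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def reference_signatures():
    return synthetic_reference_signatures()


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-case cohort shared by read-only tests."""
    cfg = CohortConfig(n_cases=30, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
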