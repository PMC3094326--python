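import numpy as np
import pytest

from subtypeforge import SyntheticConfig, generate_cohort

#: canonical seed for the default study-condition cohort used across tests
COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (study-sized, fixed seed): (expr, clinical, truth)."""
    return generate_cohort(SyntheticConfig(seed=COHORT_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
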