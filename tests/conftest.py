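import numpy as np
import pytest
from hypothesis import settings

from grsoss.simulate import default_config, generate_cohort

# property tests must behave identically on every run
settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_small():
    """A modest synthetic cohort shared by read-only tests."""
    return generate_cohort(default_config(n_case=300, n_control=500, seed=11))


@pytest.fixture(scope="session")
def cohort_full():
    """A cohort at the published group sizes (549 cases / 1036 controls)."""
    return generate_cohort(default_config(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
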