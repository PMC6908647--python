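import numpy as np
import pytest

from methmarker.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 3 cancer types, 100 tumors / 100 normals
    each, 4 specific + 6 shared planted markers, hyper_delta 0.4."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (50/50 per type) for recovery experiments."""
    return generate_cohort(CohortConfig(n_tumors=50, n_normals=50, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
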