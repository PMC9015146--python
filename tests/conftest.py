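import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests."""
    from hvindex import SyntheticConfig, generate_cohort
    return generate_cohort(SyntheticConfig(seed=1))
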