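import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests."""
    from apakit import simulate_cohort

    return simulate_cohort(seed=20240901)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
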