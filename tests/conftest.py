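import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def geweke_zs():
    """One shared Geweke successive-conditional run (moderately expensive)."""
    from support import geweke_zscores

    return geweke_zscores(n_marginal=4000, n_successive=9000, seed=1234)
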