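import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_suite():
    """Seeded synthetic recordings at the discrimination-band centres."""
    from nanopipette.synth import make_fixture_suite

    return make_fixture_suite(seed=20240204)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
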