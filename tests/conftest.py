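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


@pytest.fixture(scope="session")
def default_spec():
    from wmhtraj.phantom import PhantomSpec

    return PhantomSpec()


@pytest.fixture(scope="session")
def subject(default_spec):
    """One default-spec subject shared across the session (read-only)."""
    from wmhtraj.phantom import make_subject_phantom

    return make_subject_phantom(default_spec, 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
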