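import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drscreen import THREE_CLASS, TWO_CLASS, screening_preset, gen_prob_records

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three():
    return THREE_CLASS


@pytest.fixture(scope="session")
def two():
    return TWO_CLASS


@pytest.fixture(scope="session")
def screening_records():
    """10k labelled synthetic probability records, screening preset."""
    return gen_prob_records(screening_preset(10_000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
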