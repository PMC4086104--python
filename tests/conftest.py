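import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from primerwalk import BufferConditions, load_nn_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def santalucia():
    return load_nn_table("santalucia1998")


@pytest.fixture(scope="session")
def breslauer():
    return load_nn_table("breslauer1986")


@pytest.fixture
def buffer_default():
    """50 mM monovalent, 500 nM primer, 0.5 nM template, simplified K."""
    return BufferConditions()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
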