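import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from impulsepm import make_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def baseline_cfg():
    return make_fixture("baseline_system1", 0)


@pytest.fixture(scope="session")
def stage_cfg():
    return make_fixture("stage_mixture", 0)


@pytest.fixture(scope="session")
def sweep_cfg():
    return make_fixture("stochastic_sweep", 42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
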