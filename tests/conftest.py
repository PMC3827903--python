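import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def bone_preset():
    from trailforge import get_preset

    return get_preset("bone_rough")


@pytest.fixture(scope="session")
def dentin_preset():
    from trailforge import get_preset

    return get_preset("dentin_rough")


@pytest.fixture(scope="session")
def donor1():
    from trailforge import get_donor

    return get_donor("donor1_exp1")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
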