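import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def panel():
    from nanobracket.datasets import reference_panel

    return reference_panel()


@pytest.fixture
def experiments():
    from nanobracket.datasets import let7b_experiments

    return let7b_experiments()
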