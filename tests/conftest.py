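import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_spec():
    from diffage.phantom import PhantomSpec

    return PhantomSpec(noise_sd=0.0)


@pytest.fixture
def default_spec():
    from diffage.phantom import PhantomSpec

    return PhantomSpec()
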