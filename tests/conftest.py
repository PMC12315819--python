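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
def default_field():
    """One standard synthetic field (~50 spots/channel at peak-SNR ~10)."""
    from coagg import SynthFieldParams, generate_field
    return generate_field(SynthFieldParams(seed=3))


@pytest.fixture
def blank_params():
    from coagg import SynthFieldParams
    return SynthFieldParams(lambda_pair=0, lambda_red_only=0,
                            lambda_blue_only=0, seed=11)
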