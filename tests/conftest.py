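import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from redoxniche import SyntheticLakeParams, generate_snapshot

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def quiet_params() -> SyntheticLakeParams:
    """Noise-free defaults (euxinic-basin snapshot)."""
    return SyntheticLakeParams(noise_sd_fraction=0.0, seed=7)


@pytest.fixture
def quiet_snapshot(quiet_params):
    return generate_snapshot(quiet_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210718)
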