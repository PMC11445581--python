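import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fccskit.types import ObservationVolume

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def volume() -> ObservationVolume:
    """Calibrated confocal volume used throughout: w_xy = 0.2 µm, kappa = 5,
    V_eff ~ 0.2227 fL."""
    return ObservationVolume(w_xy=0.2, kappa=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
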