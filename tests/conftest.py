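import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from fflmpi import phantoms, protocols  # noqa: E402


@pytest.fixture(scope="session")
def small_protocol():
    """Human-like protocol scaled down for fast unit tests (noiseless)."""
    return protocols.human_preset(
        n_projections=8, n_points=11, periods_per_point=8,
        noise_sigma=0.0, n_averages=1)


@pytest.fixture(scope="session")
def noisy_small_protocol(small_protocol):
    return small_protocol.replace(noise_sigma=9.77e-9)


@pytest.fixture(scope="session")
def center_point_phantom():
    """22 ng Fe point sample at the isocenter."""
    return phantoms.phantom_preset("point_22ng")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
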