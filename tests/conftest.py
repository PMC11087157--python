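import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icmreduce import ContrastModel, GridSpec, NoiseModel, dect_phantom

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def contrast():
    return ContrastModel()


@pytest.fixture(scope="session")
def unit_noise():
    """Noise model with unit recon factor at reference size/dose."""
    return NoiseModel(sigma_ref=10.0, recon_factors={"ir": 1.0})


@pytest.fixture(scope="session")
def grid():
    return GridSpec(pixel_spacing=2.5, n_slices=3, slice_thickness=5.0)


@pytest.fixture(scope="session")
def small_phantom():
    return dect_phantom("small_adult")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
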