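import numpy as np
import pytest
from hypothesis import settings

from ibccad.config import default_type1_config, default_type2_config
from ibccad.features import load_reference_cohort
from ibccad.phantom import (
    PhantomParams,
    SidePhantomParams,
    generate_bilateral_phantom,
)

settings.register_profile("suite", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort():
    return load_reference_cohort()


@pytest.fixture(scope="session")
def t1_config():
    return default_type1_config()


@pytest.fixture(scope="session")
def t2_config():
    return default_type2_config()


@pytest.fixture(scope="session")
def symmetric_study():
    """Noise-free CC phantom with identical constant-band sides."""
    side = SidePhantomParams(skin_band_intensity_sd=0.0)
    params = PhantomParams(noise_sd=0.0, seed=5, right=side, left=side)
    study, truth = generate_bilateral_phantom(params)
    return params, study, truth


@pytest.fixture(scope="session")
def asymmetric_study():
    """Noise-free CC phantom: right band intensity 0.8, left 0.4."""
    params = PhantomParams(
        noise_sd=0.0,
        seed=4,
        right=SidePhantomParams(skin_band_intensity=0.8),
        left=SidePhantomParams(skin_band_intensity=0.4),
    )
    study, truth = generate_bilateral_phantom(params)
    return params, study, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
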