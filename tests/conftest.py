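import numpy as np
import pytest

from favf.imaging_model import OpticsConfig


@pytest.fixture(scope="session")
def optics() -> OpticsConfig:
    """Default virtual microscope."""
    return OpticsConfig()


@pytest.fixture(scope="session")
def optics_noise_free() -> OpticsConfig:
    return OpticsConfig(noise_sigma=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
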