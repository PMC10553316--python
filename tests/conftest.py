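import numpy as np
import pytest

from stainquant import SlideParams, generate_slide


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_slide():
    """A modest default-style slide (disk tissue + stain + defocused dirt)."""
    params = SlideParams(canvas=(360, 360), object_radius_frac=0.75)
    return generate_slide(params, seed=99)


@pytest.fixture(scope="session")
def tiny_params():
    """Parameters for quick batch tests."""
    return SlideParams(canvas=(240, 240), object_radius_frac=0.7, n_noise_blobs=1)
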