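import numpy as np
import pytest

from octeb.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def two_band_image():
    """Noiseless 200x400 image: bright (0.8) above row 50, dark (0.2) below."""
    img = np.full((200, 400), 0.2)
    img[:50] = 0.8
    return img


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A small three-boundary phantom spec for fast benchmark-level tests."""
    return PhantomSpec(
        height=100,
        width=120,
        mean_depths=(20.0, 50.0, 80.0),
        layer_intensities=(0.1, 0.7, 0.3, 0.6),
        undulation_amplitude=3.0,
        undulation_smoothness=20.0,
        min_gap=8.0,
    )


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec speckled phantom and its ground truth."""
    return make_phantom(PhantomSpec(seed=7))
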