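import numpy as np
import pytest

from amac import PhantomSpec, ThresholdScheme, make_phantom_section


@pytest.fixture
def scheme():
    return ThresholdScheme()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_section():
    spec = PhantomSpec(canvas=(128, 128), outer_radius=50, inner_radius=28,
                       infarct_angle=100, fibrosis_density=0.02,
                       hue_jitter=0, seed=7)
    return make_phantom_section(spec)


def random_rgb_image(rng, h=64, w=64, alpha=False):
    """Random 8-bit image spanning the full channel range."""
    c = 4 if alpha else 3
    return rng.integers(0, 256, size=(h, w, c), dtype=np.uint8)
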