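import numpy as np
import pytest

from biomotion.gabor import build_dictionary
from biomotion.synth import BarSpec, gen_bar_images


@pytest.fixture(scope="session")
def small_dictionary():
    """4 orientations, 1 scale, 7 px kernels — fits 16x16 frames."""
    return build_dictionary(n_orientations=4, n_scales=1, base_size=7)


@pytest.fixture(scope="session")
def dictionary8():
    """8 orientations, 1 scale, 11 px kernels."""
    return build_dictionary(n_orientations=8, n_scales=1, base_size=11)


@pytest.fixture(scope="session")
def vertical_bar_frames():
    """5 noisy 48x48 images each containing one near-vertical bar."""
    frames, manifest = gen_bar_images(
        BarSpec(shape=(48, 48), seed=0, orientation=np.pi / 2,
                noise_sigma=0.1, n_images=5))
    return frames, manifest
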