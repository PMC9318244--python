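import numpy as np
import pytest

from lesionfd.synthetic import Illumination, SyntheticLesionParams, render_lesion

# small-canvas parameters keep unit tests fast; the package defaults use a
# larger canvas sized for the shape-FD scale series
SMALL = dict(image_width=320, image_height=320, base_radius=90.0, harmonics=24)


@pytest.fixture(scope="session")
def small_lesion_params() -> SyntheticLesionParams:
    return SyntheticLesionParams(seed=7, **SMALL)


@pytest.fixture(scope="session")
def small_lesion(small_lesion_params):
    return render_lesion(small_lesion_params)


@pytest.fixture(scope="session")
def disc_image():
    """Clean dark disc (intensity 60) on a saturated white background."""
    h = w = 256
    yy, xx = np.indices((h, w))
    mask = np.hypot(yy - 127.5, xx - 127.5) <= 80
    img = np.where(mask, 60, 255).astype(np.uint8)
    return img, mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
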