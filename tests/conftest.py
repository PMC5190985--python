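import numpy as np
import pytest
from skimage.color import hsv2rgb

from vinelai.segmentation import LEAF_REFERENCE_HSB, SKY_REFERENCE_HSB


def hsb_to_rgb8(hue_deg: float, sat: float, bri: float) -> np.ndarray:
    """One HSB color as a uint8 RGB triple (same conversion path as the renderer)."""
    hsv = np.array([[[hue_deg / 360.0, sat, bri]]])
    return (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)[0, 0]


@pytest.fixture(scope="session")
def sky_rgb() -> np.ndarray:
    return hsb_to_rgb8(*SKY_REFERENCE_HSB)


@pytest.fixture(scope="session")
def leaf_rgb() -> np.ndarray:
    return hsb_to_rgb8(*LEAF_REFERENCE_HSB)


@pytest.fixture
def two_tone_image(sky_rgb, leaf_rgb):
    """Factory: an image with an exact sky proportion from the reference palette."""

    def build(sky_fraction: float, shape=(50, 40)) -> np.ndarray:
        h, w = shape
        n = h * w
        n_sky = round(sky_fraction * n)
        flat = np.empty((n, 3), dtype=np.uint8)
        flat[:n_sky] = sky_rgb
        flat[n_sky:] = leaf_rgb
        return flat.reshape(h, w, 3)

    return build
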