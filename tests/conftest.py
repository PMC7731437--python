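import numpy as np
import pytest

from quadratcover.imaging import NormalizedImage, RawImage, preprocess_image


def norm_image(red, green, blue) -> NormalizedImage:
    """Build a NormalizedImage directly from band arrays (test shortcut)."""
    return NormalizedImage(
        red=np.asarray(red, dtype=float),
        green=np.asarray(green, dtype=float),
        blue=np.asarray(blue, dtype=float),
    )


def random_raw_image(rng, height, width) -> RawImage:
    """A random, almost-surely non-degenerate RGB image."""
    return RawImage(
        pixels=rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_normalized(rng):
    """Factory for random preprocessed images."""

    def make(height=32, width=32):
        return preprocess_image(random_raw_image(rng, height, width))

    return make
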