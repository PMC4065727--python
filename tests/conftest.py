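import numpy as np
import pytest

from nanomat import GrayscaleImage, IntensityHistogram, intensity_histogram


@pytest.fixture
def two_level_image() -> GrayscaleImage:
    """10x10 image with 40 pixels at level 50 and 60 at level 200."""
    px = np.concatenate([np.full(40, 50), np.full(60, 200)]).reshape(10, 10)
    return GrayscaleImage(px.astype(np.uint8), source_id="two-level")


@pytest.fixture
def two_level_hist(two_level_image) -> IntensityHistogram:
    return intensity_histogram(two_level_image)


def make_hist(mu: float, sigma: float, a: int, b: int) -> IntensityHistogram:
    """Histogram stub with prescribed summary statistics for scheme tests."""
    counts = np.zeros(256, dtype=np.int64)
    counts[a] = 1
    counts[b] = 1
    return IntensityHistogram(counts=counts, total=2, a=a, b=b, mu=mu, sigma=sigma)
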