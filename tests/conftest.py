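import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_gray(rng):
    """A 32x32 noise ROI with a centered disk mask."""
    from osteofract import GrayscaleROI

    pixels = rng.integers(0, 256, (32, 32), dtype=np.uint8)
    yy, xx = np.indices((32, 32))
    mask = (yy - 16) ** 2 + (xx - 16) ** 2 < 100
    return GrayscaleROI(pixels, mask=mask, image_id="fixture")
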