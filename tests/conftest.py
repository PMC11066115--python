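import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from skimage.draw import disk as draw_disk

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
    return np.random.default_rng(12345)


def make_disk_image(shape, center, radius, contrast=1.0):
    """Bright disk phantom on a dark background."""
    img = np.zeros(shape, dtype=np.float64)
    rr, cc = draw_disk(center, radius, shape=shape)
    img[rr, cc] = contrast
    return img


def make_disk_mask(shape, center, radius):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    mask[rr, cc] = True
    return mask


def tube_mask(shape, p0, p1, half_width):
    """Analytic tube mask: pixels within half_width of the segment p0-p1."""
    from camangio.synth_cine import _distance_to_polyline

    line = np.asarray([p0, p1], dtype=np.float64)
    return _distance_to_polyline(shape, line) <= half_width
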