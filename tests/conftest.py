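import numpy as np
import pytest


def render_spots(shape, spots, sigma=2.1, background=10.0):
    """Render isotropic Gaussian spots: spots = [(x, y, amplitude), ...]."""
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    for x, y, amp in spots:
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))
    return img


def match_points(found, planted, radius):
    """Greedy matching of found (x, y) to planted (x, y); returns n_matched."""
    planted = list(planted)
    n = 0
    for fx, fy in found:
        best, bi = None, None
        for i, (px, py) in enumerate(planted):
            d = np.hypot(fx - px, fy - py)
            if d <= radius and (best is None or d < best):
                best, bi = d, i
        if bi is not None:
            planted.pop(bi)
            n += 1
    return n


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
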