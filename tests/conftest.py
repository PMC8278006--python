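import numpy as np
import pytest

from aisquant.profiles import AIS, DENDRITE, IntensityProfile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_profile(values, pixel=0.28, compartment=AIS, subtracted=False):
    return IntensityProfile.from_intensities(values, pixel, compartment,
                                             background_subtracted=subtracted)


def gaussian_bump_profile(sigma_px, pixel=1.0, amp=100.0, n_sigma=12, center_offset_px=0.0):
    """Noiseless Gaussian bump sampled on a pixel grid, peak near the middle."""
    n = int(n_sigma * sigma_px) + 1
    x = np.arange(n) * pixel
    center = (n // 2 + center_offset_px) * pixel
    values = amp * np.exp(-((x - center) ** 2) / (2 * (sigma_px * pixel) ** 2))
    return make_profile(values, pixel, subtracted=True)


@pytest.fixture
def bump_profile():
    return gaussian_bump_profile(sigma_px=8.0)
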