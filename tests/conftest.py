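import numpy as np
import pytest

from tendonqus.roi_io import PixelCalibration, UltrasoundImage


@pytest.fixture
def rng():
    return np.random.default_rng(20160817)


@pytest.fixture
def cal_01mm():
    """0.1 mm/pixel calibration used by most geometric examples."""
    return PixelCalibration(spacing_mm=0.1)


def make_image(pixels, view="longitudinal", spacing_mm=0.1):
    return UltrasoundImage(
        pixels=np.asarray(pixels, dtype=np.uint8),
        calibration=PixelCalibration(spacing_mm=spacing_mm),
        view=view,
    )


@pytest.fixture
def image_factory():
    return make_image
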