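import numpy as np
import pytest

from embolitrack.detection import DetectionParams, RegionOfInterest
from embolitrack.io_core import Calibration, Frame
from embolitrack.reconstruction import LinkingParams


@pytest.fixture
def calibration() -> Calibration:
    return Calibration.isotropic(0.1, 25.0)


@pytest.fixture
def unit_calibration() -> Calibration:
    """1 mm per px, 1 Hz: pixel and physical coordinates coincide."""
    return Calibration.isotropic(1.0, 1.0)


@pytest.fixture
def full_roi() -> RegionOfInterest:
    return RegionOfInterest.from_rect(0, 0, 99, 99)


def make_frame(pixels: np.ndarray, index: int = 0, frame_rate: float = 25.0) -> Frame:
    return Frame(np.asarray(pixels, dtype=float), index=index, time=index / frame_rate)


@pytest.fixture
def permissive_params() -> DetectionParams:
    return DetectionParams(
        grey_threshold=100.0,
        aspect_ratio_min=0.05,
        area_min_px=1.0,
        area_max_px=1e6,
        circularity_min=0.05,
    )


@pytest.fixture
def default_linking() -> LinkingParams:
    return LinkingParams()
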