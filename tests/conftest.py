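import numpy as np
import pytest

from octacnv.cohort_stats import IMPROVED, NOT_IMPROVED, EyeRecord
from octacnv.morphometry import BinaryMask, EnFaceImage, RegionOfInterest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_level_image():
    """ROI with exactly two intensity levels: 10 (background) and 200 (vessel)."""
    pixels = np.full((32, 32), 10, dtype=np.uint8)
    pixels[8:24, 8:24] = 200
    image = EnFaceImage(pixels=pixels, nominal_pixel_size=10.0, axial_length=23.95)
    roi = RegionOfInterest(mask=np.ones((32, 32), dtype=bool))
    return image, roi


@pytest.fixture
def horizontal_bar_mask():
    """3-pixel-thick horizontal bar, 50 px long."""
    mask = np.zeros((20, 60), dtype=bool)
    mask[9:12, 5:55] = True
    return BinaryMask(mask=mask, pixel_size=10.0)


@pytest.fixture
def plus_sign_mask():
    """Two crossing 1-px bars meeting at one junction."""
    mask = np.zeros((41, 41), dtype=bool)
    mask[20, 5:36] = True
    mask[5:36, 20] = True
    return BinaryMask(mask=mask, pixel_size=10.0)


def make_table_cohort(a, b, c, d, variable, level1, level0):
    """34-eye style cohort embedding the 2x2 counts (a,b;c,d).

    Rows are outcome groups (improved first); columns are predictor levels
    with the coded-1 level first.
    """
    records = []
    i = 0
    for outcome, n1, n0 in ((IMPROVED, a, b), (NOT_IMPROVED, c, d)):
        for level, n in ((level1, n1), (level0, n0)):
            for _ in range(n):
                rec = EyeRecord(eye_id=f"e{i:03d}", outcome=outcome)
                setattr(rec, variable, level)
                i += 1
                records.append(rec)
    return records
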