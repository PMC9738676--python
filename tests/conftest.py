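import numpy as np
import pytest

from stereotrap.stereo_core import RectifiedPair, StereoRig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rig():
    return StereoRig(baseline_m=0.5, focal_px=1000.0, image_width=64, image_height=48)


def make_shifted_pair(rng, shape=(32, 48), shift=4, lo=0.0, hi=255.0):
    """Left = random texture; right = left shifted left by `shift` columns.

    Dis-occluded right-edge columns get fresh texture.  Interior left pixels
    with column >= shift have an exact correspondence at disparity `shift`.
    """
    H, W = shape
    left = rng.uniform(lo, hi, size=(H, W))
    # right(i - shift) = left(i): scene content moves left in the right image
    right = rng.uniform(lo, hi, size=(H, W))
    right[:, : W - shift] = left[:, shift:]
    return RectifiedPair(left=left, right=right)


@pytest.fixture
def shifted_pair(rng):
    return make_shifted_pair(rng)
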