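import sys
from pathlib import Path

import numpy as np
import pytest
from PIL import Image

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from myotubekit.mask import BinaryMask, label_myotubes
from myotubekit.preprocessing import ChannelImage, PixelCalibration


@pytest.fixture
def calib() -> PixelCalibration:
    """1 um per pixel: pixel and micron coordinates coincide."""
    return PixelCalibration(1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def channel(pixels, role="myotube", mpp=1.0) -> ChannelImage:
    return ChannelImage(np.asarray(pixels, dtype=float), role, PixelCalibration(mpp))


def binary(pixels, mpp=1.0) -> BinaryMask:
    return BinaryMask(np.asarray(pixels, dtype=bool), PixelCalibration(mpp))


def labeled(pixels, mpp=1.0):
    return label_myotubes(binary(pixels, mpp))


def ribbon_mask(shape, r0, c0, r1, c1, width):
    """Constant-width ribbon between two points (exact geometry)."""
    from scipy.ndimage import distance_transform_edt
    from skimage.draw import line

    m = np.zeros(shape, dtype=bool)
    rr, cc = line(r0, c0, r1, c1)
    m[rr, cc] = True
    return distance_transform_edt(~m) <= width / 2.0


def write_png(path: Path, array: np.ndarray, mode: str = "L") -> Path:
    Image.fromarray(array, mode=mode).save(path)
    return path
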