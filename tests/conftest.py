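import numpy as np
import pytest

from caliper3vv.geometry import AO, PA, SVC, LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def square_mask(shape=(20, 20), top=5, left=5, size=5, class_code=PA):
    grid = np.zeros(shape, dtype=int)
    grid[top : top + size, left : left + size] = class_code
    return LabelMask(grid)


def two_vessel_mask(shape=(60, 120)):
    """PA and Ao as translated copies of the same 9x9 square; SVC absent."""
    grid = np.zeros(shape, dtype=int)
    grid[20:29, 20:29] = PA
    grid[20:29, 70:79] = AO
    return LabelMask(grid)


@pytest.fixture
def paired_vessel_mask():
    return two_vessel_mask()
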