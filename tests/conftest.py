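import numpy as np
import pytest

from navseg import BinaryMask, GridSpec


@pytest.fixture
def unit_grid():
    """20^3 grid, 1 mm isotropic, origin at world zero, axes aligned."""
    return GridSpec(shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


def make_cube_mask(grid: GridSpec, lo, hi, label: str = "") -> BinaryMask:
    """Axis-aligned cube of foreground voxels with index slices [lo, hi)."""
    data = np.zeros(grid.shape, dtype=bool)
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return BinaryMask(data, grid, label=label)


@pytest.fixture
def cube_mask(unit_grid):
    return make_cube_mask(unit_grid, (5, 5, 5), (13, 13, 13), label="tumor")
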