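import numpy as np
import pytest

from pvspatial.grid import VoxelGrid3D


def grid_from_voxels(voxels, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    """Binary grid with foreground at the given index triples."""
    arr = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        arr[tuple(v)] = 1
    return VoxelGrid3D(arr, spacing)


@pytest.fixture
def cube333():
    """Solid 3x3x3 cube inside an 5x5x5 volume."""
    arr = np.zeros((5, 5, 5), dtype=np.uint8)
    arr[1:4, 1:4, 1:4] = 1
    return VoxelGrid3D(arr)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
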