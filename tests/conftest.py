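import numpy as np
import pytest

from volcoloc import ColocParams, MultiChannelStack, VoxelGrid, full_volume_mask


@pytest.fixture
def hand_stack():
    """The four-voxel worked example: A = (4, 2, 0, 1), B = (0, 2, 4, 1)."""
    a = np.array([[[4, 2, 0, 1]]], dtype=np.uint8)
    b = np.array([[[0, 2, 4, 1]]], dtype=np.uint8)
    return MultiChannelStack(channels=(
        VoxelGrid(a, bit_depth=8), VoxelGrid(b, bit_depth=8),
    ))


@pytest.fixture
def hand_params():
    return ColocParams(ch_a=0, ch_b=1, low_a=1, high_a=4, low_b=1, high_b=4)


@pytest.fixture
def hand_roi(hand_stack):
    return full_volume_mask(hand_stack)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_stack(rng, max_side=16, n_channels=2, spacing=(0.4, 0.1, 0.1)):
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    channels = tuple(
        VoxelGrid(rng.integers(0, 256, shape, dtype=np.uint8).astype(np.uint8),
                  bit_depth=8, spacing=spacing)
        for _ in range(n_channels)
    )
    return MultiChannelStack(channels=channels)


def random_roi(rng, stack):
    nz, ny, nx = stack.shape
    from volcoloc import RoiMask

    footprint = rng.random((ny, nx)) < 0.7
    if not footprint.any():
        footprint[0, 0] = True
    z_front = int(rng.integers(0, nz))
    z_back = int(rng.integers(z_front, nz))
    return RoiMask(footprint, z_front, z_back)
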