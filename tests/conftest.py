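import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from pyporoscope import BinaryVolume, GrayVolume, PhantomSpec, generate_binary_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_gray():
    def make(shape=(12, 12, 12), seed=0, dtype=np.uint8, voxel_size=1.0):
        r = np.random.default_rng(seed)
        info = np.iinfo(dtype)
        data = r.integers(0, info.max + 1, size=shape, dtype=dtype)
        return GrayVolume(data, voxel_size)

    return make


@pytest.fixture
def random_mask():
    def make(shape=(10, 10, 10), seed=0, p=0.5, voxel_size=1.0):
        r = np.random.default_rng(seed)
        return BinaryVolume(r.random(shape) < p, voxel_size)

    return make


@pytest.fixture
def ball_volume():
    def make(r, shape=None, voxel_size=1.0, center=None):
        if shape is None:
            n = int(2 * r + 12)
            shape = (n, n, n)
        params = {"r": r}
        if center is not None:
            params["center"] = center
        return generate_binary_phantom(
            PhantomSpec("ball", shape, voxel_size=voxel_size, params=params)
        )

    return make
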