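import numpy as np
import pytest

from skeltube import make_fixture


@pytest.fixture(scope="session")
def straight_tube():
    return make_fixture("straight_tube")


@pytest.fixture(scope="session")
def y_junction():
    return make_fixture("y_junction")


@pytest.fixture(scope="session")
def single_voxel():
    return make_fixture("single_voxel")


@pytest.fixture(scope="session")
def two_blobs():
    return make_fixture("two_blobs")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def neighbor_degree(skel: np.ndarray, voxel) -> int:
    """Brute-force count of foreground 26-neighbors of one skeleton voxel."""
    z, y, x = voxel
    deg = 0
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                zz, yy, xx = z + dz, y + dy, x + dx
                if (0 <= zz < skel.shape[0] and 0 <= yy < skel.shape[1]
                        and 0 <= xx < skel.shape[2] and skel[zz, yy, xx]):
                    deg += 1
    return deg
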