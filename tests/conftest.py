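import numpy as np
import pytest

from arterial_atlas import (
    BinaryVolume,
    VolumeGrid,
    make_phantom,
    sample_cohort,
)


@pytest.fixture(scope="session")
def grid16():
    return VolumeGrid((16, 16, 16))


@pytest.fixture(scope="session")
def phantom32():
    """Standard 32^3 phantom: 4 territories, planted K* = (1, 2, 2, 3)."""
    return make_phantom((32, 32, 32), 4, (1, 2, 2, 3), seed=7)


@pytest.fixture(scope="session")
def cohort32(phantom32):
    """Cohort of 50 subjects per territory, 40% right-hemisphere."""
    return sample_cohort(phantom32, 50, right_fraction=0.4, seed=11)


@pytest.fixture(scope="session")
def phantom16():
    """Small phantom for brute-force oracles."""
    return make_phantom((16, 16, 16), 3, (1, 1, 2), seed=3)


@pytest.fixture(scope="session")
def cohort16(phantom16):
    return sample_cohort(phantom16, 30, right_fraction=0.0, seed=5)


def random_mask(grid: VolumeGrid, rng, p=0.2) -> BinaryVolume:
    return BinaryVolume(grid, (rng.random(grid.shape) < p).astype(np.uint8))
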