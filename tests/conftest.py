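import numpy as np
import pytest

from vascband.grid import VoxelVolume
from vascband.phantom import make_nodule_phantom


@pytest.fixture(scope="session")
def sphere10():
    """Digitized 10 mm sphere at 0.5 mm isotropic spacing, small margin."""
    return make_nodule_phantom(10.0, (0.5, 0.5, 0.5), margin_mm=4.0)


@pytest.fixture(scope="session")
def vessel_grid():
    """Empty 50 mm cube at 0.5 mm spacing for tube rasterization."""
    return VoxelVolume(np.zeros((100, 100, 100), dtype=np.uint8), (0.5, 0.5, 0.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
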