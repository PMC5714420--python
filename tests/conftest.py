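import numpy as np
import pytest

import cobaltmc as cm


@pytest.fixture
def stream():
    return cm.RandomStream(12345)


@pytest.fixture(scope="session")
def small_water_grid():
    """Coarse water tank for fast transport tests."""
    return cm.make_water_phantom(voxel_size=(0.508, 0.508, 0.5))


@pytest.fixture(scope="session")
def water_column():
    """Tall homogeneous water column for free-path statistics."""
    hu = np.zeros((8, 8, 400), dtype=np.float32)
    return cm.VoxelGrid.from_hu(hu, voxel_size=(2.0, 2.0, 0.5))


@pytest.fixture
def pencil_photon(water_column):
    return cm.Photon(position=[0.0, 0.0, water_column.z_top],
                     direction=[0.0, 0.0, -1.0], energy=1.25)
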