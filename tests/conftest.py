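import numpy as np
import pytest

from tlct.geometry import GeometryConfig, SensitivityProfile
from tlct.phantoms import shepp_logan
from tlct.projector import weighted_forward_project


@pytest.fixture(scope="session")
def small_geometry():
    """Odd-sized geometry: the rotation center falls on a voxel center."""
    return GeometryConfig(n_angles=45, n_detector=65, image_shape=(65, 65))


@pytest.fixture(scope="session")
def small_profile():
    return SensitivityProfile(extent=65)


@pytest.fixture(scope="session")
def geometry64():
    return GeometryConfig(n_angles=64, n_detector=64, image_shape=(64, 64),
                          angle_offset=float(np.pi / 2))


@pytest.fixture(scope="session")
def profile64():
    return SensitivityProfile(extent=64)


@pytest.fixture(scope="session")
def phantom64():
    return shepp_logan(64)


@pytest.fixture(scope="session")
def weighted_sino64(phantom64, geometry64, profile64):
    return weighted_forward_project(phantom64, geometry64, profile64)
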