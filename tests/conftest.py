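import numpy as np
import pytest

import caslquant as cq


@pytest.fixture
def geometry():
    """Acquisition-matched volume geometry: 5 slices, 260x400 um in-plane."""
    return cq.VolumeGeometry(
        voxel_size_xy=(260.0, 400.0), slice_thickness=800.0, n_slices=5, matrix=(32, 32)
    )


@pytest.fixture
def params():
    """Protocol constants with a measured labelling efficiency of 0.85."""
    return cq.AcquisitionParams(alpha=0.85)


@pytest.fixture
def phantom(geometry):
    """12-region nested phantom spanning CBF 30-250 ml/100g/min."""
    return cq.default_phantom(geometry)


@pytest.fixture
def uniform_phantom():
    """Single-region, single-slice phantom for closed-form checks."""
    geom = cq.VolumeGeometry(
        voxel_size_xy=(260.0, 400.0), slice_thickness=800.0, n_slices=1, matrix=(12, 12)
    )
    return cq.make_phantom(
        geom, 1, {"cbf": [100.0], "t1": [1700.0], "m0": [1000.0]}
    )


@pytest.fixture
def smooth_test_volume(geometry):
    """Smooth two-blob volume with quiet borders, for registration tests."""
    x, y, z = np.meshgrid(np.arange(32), np.arange(32), np.arange(5), indexing="ij")
    vol = 100.0 * np.exp(-((x - 16) ** 2 / 60 + (y - 14) ** 2 / 40 + (z - 2) ** 2 / 3))
    vol += 20.0 * np.exp(-((x - 10) ** 2 / 20 + (y - 20) ** 2 / 25 + (z - 3) ** 2 / 2))
    return vol
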