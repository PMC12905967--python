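import numpy as np
import pytest

import conntarget as ct
from conntarget.signal import BoldSeries
from conntarget.volumes import VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_grid():
    """10x10x10 lattice, 2-mm voxels, origin at (0,0,0) mm."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return VoxelGrid((10, 10, 10), affine)


@pytest.fixture
def identity_grid():
    return VoxelGrid((10, 10, 10), np.eye(4))


def make_bold(grid, data, tr=1.0):
    return BoldSeries(grid=grid, data=data, tr=tr)


@pytest.fixture
def tiny_bold(tiny_grid, rng):
    """Random 40-frame series on the tiny grid."""
    return make_bold(tiny_grid, rng.standard_normal((40, tiny_grid.n_voxels)))


@pytest.fixture(scope="session")
def phantom():
    """One default-scale phantom, shared across tests (seeded)."""
    return ct.make_phantom(ct.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom_target(phantom):
    """Connectivity map and target report computed once from the phantom."""
    proc = ct.smooth_gaussian(ct.highpass(phantom.pre, 0.01), 4.0)
    seed = ct.seedmap_series(proc, phantom.group_weights, phantom.gm_mask, phantom.dlpfc_mask)
    cmap = ct.map_connectivity(proc, seed, phantom.dlpfc_mask)
    return cmap, ct.locate_target(cmap)
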