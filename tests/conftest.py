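import numpy as np
import pytest

from octamnv import ScanGrid, phantoms


@pytest.fixture(scope="session")
def grid6mm() -> ScanGrid:
    """6 × 6-mm scan at 12-µm lateral / 4-µm axial sampling."""
    return ScanGrid(nx=500, ny=500, pitch_x=12.0, pitch_y=12.0, pitch_z=4.0)


@pytest.fixture(scope="session")
def grid_small() -> ScanGrid:
    """Small 2.4 × 2.4-mm grid for cheap unit tests."""
    return ScanGrid(nx=200, ny=200, pitch_x=12.0, pitch_y=12.0, pitch_z=4.0)


@pytest.fixture(scope="session")
def lesion_phantom(grid6mm):
    return phantoms.make_lesion_phantom(grid6mm, seed=3, noise_sd=0.05)


@pytest.fixture(scope="session")
def lesion_phantom_clean(grid6mm):
    return phantoms.make_lesion_phantom(grid6mm, seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def cc_phantom_with_disks(grid6mm, lesion_phantom):
    rng = np.random.default_rng(100)
    disks = phantoms.random_fd_disks(
        grid6mm, rng, forbidden=lesion_phantom.truth_mnv.pixels
    )
    return phantoms.make_cc_phantom(grid6mm, seed=7, fd_disks=disks, speckle_sd=0.05)


@pytest.fixture(scope="session")
def choroid_grid() -> ScanGrid:
    """Coarser grid for 3-D choroid phantoms (keeps volumes small)."""
    return ScanGrid(nx=250, ny=250, pitch_x=24.0, pitch_y=24.0, pitch_z=8.0)
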