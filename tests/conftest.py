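import numpy as np
import pytest

from bonefrag.microfe import MaterialBinning, build_fe_model
from bonefrag.phantoms import VoxelVolume


@pytest.fixture(scope="session")
def binning():
    return MaterialBinning()


def random_voxel_model(shape, seed, fill=0.75, tmd_range=(600.0, 1400.0),
                       voxel_um=50.0):
    """Small random z-spanning voxel FE model for solver cross-checks."""
    rng = np.random.default_rng(seed)
    while True:
        mask = rng.random(shape) < fill
        # guarantee a z-spanning column so a connected model exists
        j, i = rng.integers(shape[1]), rng.integers(shape[2])
        mask[:, j, i] = True
        data = np.where(mask, rng.uniform(*tmd_range, shape), 0.0)
        vol = VoxelVolume(data.astype(np.float32), voxel_um)
        try:
            return build_fe_model(vol, mask, MaterialBinning(),
                                  roi_radius_mm=None)
        except Exception:
            continue
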