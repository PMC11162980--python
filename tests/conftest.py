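import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from levoresp.grids import AtlasLabels, VolumeGrid
from levoresp.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-signal cohort at desk scale, shared across tests (read-only)."""
    cfg = SyntheticConfig(
        n_patients=30,
        records_per_patient=2,
        volume_shape=(32, 40, 32),
        n_rois=8,
        signal_roi_ids=(3,),
        intensity_effect=1.5,
        age_slope=-0.5,
        n_healthy=20,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_atlas():
    labels = np.zeros((12, 12, 12), dtype=np.int32)
    labels[1:4, 1:4, 1:4] = 1
    labels[6:10, 2:5, 2:5] = 2
    labels[2:6, 7:11, 6:10] = 3
    return AtlasLabels(labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_volume(data, voxel=1.0):
    return VolumeGrid(np.asarray(data, dtype=np.float32), (voxel,) * 3)
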