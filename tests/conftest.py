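import numpy as np
import pytest

from uwmc.connectivity import PairKey
from uwmc.io import BinaryMask, IntensityVolume, LabelRecord, LabelVolume
from uwmc.simulate import worked_example_config, make_phantom, multibundle_config


@pytest.fixture(scope="session")
def worked_example_phantom():
    """Two regions, four streamlines, two through the lesion (UWMC 0.5)."""
    return make_phantom(worked_example_config(seed=1))


@pytest.fixture(scope="session")
def multibundle_phantom():
    """Three one-lobe bundles of sizes 10/6/8 with targets 0.3/0.0/1.0."""
    return make_phantom(multibundle_config(seed=3))


@pytest.fixture()
def small_label_volume():
    """An 8x8x8 grid with two cubic regions (ids 3 and 9)."""
    data = np.zeros((8, 8, 8), dtype=np.int32)
    data[0:2, 3:5, 3:5] = 3
    data[6:8, 3:5, 3:5] = 9
    table = [
        LabelRecord(3, "left cube", "frontal", "L", True, False),
        LabelRecord(9, "right cube", "frontal", "R", True, False),
    ]
    return LabelVolume(data, np.eye(4), table)
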