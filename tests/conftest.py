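import numpy as np
import pytest

from lungwater.phantom import Ellipse, LABELS, ThoraxSlice
from lungwater.signal import SequenceParams, TissueParams


@pytest.fixture(scope="session")
def seq():
    return SequenceParams()


def make_disk_slice(n=32, pixel_mm=3.0, radius_mm=30.0, value_tissue=None):
    """Uniform-disk phantom as a single-ellipse thorax slice.

    The disk has a closed-form Fourier transform, making it the standard
    truth object for acquisition and reconstruction checks.
    """
    disk = Ellipse(0.0, 0.0, radius_mm, radius_mm, LABELS["chest_wall"])
    ax = (np.arange(n) - n // 2) * pixel_mm
    x, y = np.meshgrid(ax, ax, indexing="xy")
    lm = np.zeros((n, n), dtype=np.int8)
    lm[disk.contains(x, y)] = LABELS["chest_wall"]
    tissue = value_tissue or TissueParams(0.5, 900.0, 30.0)
    table = {
        LABELS["background"]: TissueParams(0.0, 1000.0, 1.0),
        LABELS["chest_wall"]: tissue,
        LABELS["left_lung"]: TissueParams(0.2, 1000.0, 5.0),
        LABELS["right_lung"]: TissueParams(0.2, 1000.0, 5.0),
        LABELS["heart"]: TissueParams(0.8, 1400.0, 35.0),
        LABELS["effusion"]: TissueParams(0.97, 2800.0, 60.0),
    }
    return ThoraxSlice(lm, table, 0.2, pixel_mm, (disk,))


@pytest.fixture(scope="session")
def disk_slice():
    return make_disk_slice()
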