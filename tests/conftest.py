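import numpy as np
import pytest

from burstsync.raster import SpikeTrain
from burstsync.segmentation import ActivePeriodSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_units():
    """Five handcrafted single units plus one MUA cluster, 2 s recording."""
    dur = 2_000
    specs = [
        ("a", [10, 50, 52, 400, 401, 990, 1500], "L2_4", "single"),
        ("b", [11, 55, 402, 995, 1501, 1502], "L2_4", "single"),
        ("c", [12, 60, 410, 1000, 1499], "L2_4", "single"),
        ("d", [300, 305, 700, 1200, 1600], "L5_6", "single"),
        ("e", [301, 306, 701, 1201], "L5_6", "single"),
        ("m1", list(range(0, 2000, 37)), "L5_6", "multi"),
    ]
    return [
        SpikeTrain(uid, np.array(t, np.int64), layer, cls, dur)
        for uid, t, layer, cls in specs
    ]


@pytest.fixture
def toy_periods():
    """Active periods for the toy raster: [0, 1100) and [1400, 2000)."""
    return ActivePeriodSet(np.array([[0, 1_100], [1_400, 2_000]]), 2_000)
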