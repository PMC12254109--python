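import math

import numpy as np
import pytest

from woundwalk.attractant import AttractantParams
from woundwalk.tracks import BinGrid, Track, WoundGeometry


@pytest.fixture
def wound():
    return WoundGeometry(center=(0.0, 0.0), radius=40.0)


@pytest.fixture
def params():
    return AttractantParams(
        q=1500.0, D=200.0, tau=18.0, m=2.5, R0=1000.0, kd=1000.0, b0=0.02, delta_r=15.0
    )


@pytest.fixture
def grid():
    return BinGrid()


@pytest.fixture
def straight_track():
    """Three collinear points marching in +x at 2 um per 0.5 min."""
    return Track("s1", t=np.array([0.0, 0.5, 1.0]), x=np.array([100.0, 102.0, 104.0]),
                 y=np.zeros(3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
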