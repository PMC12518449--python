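import numpy as np
import pytest

import peaklag as pk
from peaklag import fd_solver as fd


class FlatLandscape:
    """Stub: constant growth rate g on a huge support (oracle landscapes)."""

    components = ()

    def __init__(self, g, support=(10.0, 70.0)):
        self.g = float(g)
        self._support = support
        self.death_rate = -g
        self.epsilon = 0.1

    def __call__(self, x, t=0.0):
        return np.full_like(np.asarray(x, dtype=float), self.g)

    def frozen(self, x):
        return self(x, 0.0)

    def support_interval(self, t=0.0):
        return self._support


@pytest.fixture
def single_peak():
    """Quadratic bump (5/2 - (x-40)^2)^+ - 1/2 shifting at speed 1."""
    return pk.compose_landscape([pk.make_bump(40.0, 2.5, 2, 1.0)], 0.5,
                                epsilon=0.1)


@pytest.fixture
def fig4_landscape():
    return pk.preset("fig4")["landscape"]


@pytest.fixture
def fig4_preset():
    return pk.preset("fig4")


@pytest.fixture
def grid():
    return fd.TraitGrid(80.0, 1600)


@pytest.fixture
def coarse_grid():
    return fd.TraitGrid(80.0, 800)


@pytest.fixture
def flat_landscape():
    return FlatLandscape(2.0)
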