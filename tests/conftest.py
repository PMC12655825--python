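import numpy as np
import pytest

from activestar import ActivityParams, ForceFieldParams, SimulationParams, build_star
from activestar.topology import SystemState, _assemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_star():
    return build_star(3, 4)


@pytest.fixture
def free_bead_topology():
    """A single unbonded bead (no arms) for free-particle oracles."""
    return _assemble([])


@pytest.fixture
def ff():
    return ForceFieldParams()


def random_state(topology, rng, spread=2.0, min_dist=0.5):
    """Random non-pathological configuration (no pair closer than min_dist)."""
    n = topology.n_beads
    while True:
        pos = spread * rng.normal(size=(n, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_dist:
            return SystemState(pos, rng.normal(size=(n, 3)))


def passive_params(**kw):
    kw.setdefault("activity", ActivityParams(model="passive", fa=0.0, kBT=1.0))
    return SimulationParams(**kw)
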