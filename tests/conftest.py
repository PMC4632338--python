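import numpy as np
import pytest

from crowdlbm.lattice import LatticeConfig, SpeciesSpec
from crowdlbm.scenarios import Scenario


def make_scenario(L=100.0, dx=50.0, dt=0.625, species=None, placements=None,
                  mode="lattice", seed=0, t_end=10.0, record_every=1) -> Scenario:
    """Small custom scenario for unit tests."""
    if species is None:
        species = [SpeciesSpec("A", D0=500.0, area=100.0)]
    if placements is None:
        placements = {"A": {"kind": "random", "count": 4}}
    return Scenario("test", LatticeConfig(L=L, dx=dx, dt=dt), species,
                    placements, mode=mode, seed=seed, t_end=t_end,
                    record_every=record_every)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def single_walker_scenario():
    """One 10 nm molecule on a 50x50-site lattice, free diffusion."""
    sp = [SpeciesSpec("w", D0=500.0, area=100.0)]
    plc = {"w": {"kind": "random", "count": 1}}
    return make_scenario(L=500.0, dx=50.0, dt=1.25, species=sp, placements=plc,
                        seed=11)
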