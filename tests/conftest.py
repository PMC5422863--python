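import numpy as np
import pytest

import fpgtraj as F


@pytest.fixture(scope="session")
def toy():
    """A small toy complex with a few plant stations (session-shared,
    treat as read-only)."""
    return F.build_toy_complex(
        n_hbond_stations=3,
        bridge_station_specs=((2, 1), (3, 1), (2, 2)))


@pytest.fixture(scope="session")
def short_run(toy):
    """A 400-snapshot noiseless trajectory with known truth."""
    plan = F.PlantSpec(
        hbonds=[F.HBondPlant(0.3), F.HBondPlant(0.7), F.HBondPlant(1.0)],
        bridges=[F.BridgePlant(2, 1, 0.8), F.BridgePlant(3, 1, 0.6),
                 F.BridgePlant(2, 2, 0.5)],
        chi=F.ChiProcess((-120.0, 60.0), 0.95),
        census=F.CensusPlant(0.25),
        noise_sigma=0.0, seed=11)
    traj, manifest = F.simulate_trajectory(toy, plan, 400)
    return traj, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
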