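import logging

import numpy as np
import pytest

from scramblekit import SyntheticSpec, generate_trajectory

logging.getLogger("scramblekit").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_system():
    """Small active membrane: 80 lipids, 2 us, two scrambling sites."""
    spec = SyntheticSpec(
        n_per_leaflet={"POPC": 40},
        n_frames=2001,
        dt_ns=1.0,
        flip_rates={"POPC": {"Sec61": 2.0, "TRAP": 1.0}},
        seed=7,
    )
    traj, lipids, sites, log = generate_trajectory(spec)
    return spec, traj, lipids, sites, log


@pytest.fixture(scope="session")
def quiet_system():
    """Membrane with zero flip rate: leaflet populations must stay fixed."""
    spec = SyntheticSpec(
        n_per_leaflet={"POPC": 30},
        n_frames=1001,
        dt_ns=1.0,
        flip_rates={"POPC": {"Sec61": 0.0}},
        seed=3,
    )
    traj, lipids, sites, log = generate_trajectory(spec)
    return spec, traj, lipids, sites, log


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
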