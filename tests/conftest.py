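import numpy as np
import pytest

from swarmscape import Trajectory, preset_config, simulate
from swarmscape.couzin_sim import SwarmState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_swarm_state(rng):
    n = 20
    pos = rng.uniform(-3, 3, size=(n, 3))
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1)[:, None]
    return SwarmState(time=0.0, positions=pos, directions=d)


@pytest.fixture
def small_trajectory(rng):
    """Random-walk trajectory: 30 frames, 4 agents, uniform dt."""
    T, n = 30, 4
    steps = rng.normal(scale=0.3, size=(T, n, 3))
    positions = np.cumsum(steps, axis=0) + rng.uniform(-2, 2, size=(1, n, 3))
    return Trajectory(times=np.arange(T, dtype=float), positions=positions)


@pytest.fixture(scope="session")
def short_sim_trajectory():
    """One short simulator run shared across tests (200 frames, 10 agents)."""
    return simulate(preset_config("dpg", n_agents=10, n_steps=200, seed=7))
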