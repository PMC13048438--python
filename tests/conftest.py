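import numpy as np
import pandas as pd
import pytest

import consensus_arena as ca


@pytest.fixture(scope="session")
def global_config() -> ca.TrialConfig:
    return ca.TrialConfig(condition="global", difficulty="easy")


@pytest.fixture(scope="session")
def local_config() -> ca.TrialConfig:
    return ca.TrialConfig(condition="local", difficulty="medium")


@pytest.fixture(scope="session")
def noiseless_trial(global_config):
    """One noise-free, asocial trial: all agents head straight to the largest site."""
    table, outcome = ca.simulate_trial(global_config, ca.AgentParams.noiseless(),
                                       seed=7)
    return table, outcome


@pytest.fixture(scope="session")
def default_trial(global_config):
    """One default-calibration global trial (with social switching)."""
    cfg = ca.TrialConfig(condition="global", difficulty="hard")
    table, outcome = ca.simulate_trial(cfg, ca.AgentParams(), seed=3)
    return table, outcome


def make_table(positions: dict[str, list[tuple[float, float]]],
               config: ca.TrialConfig, dt: float = 1.0) -> ca.TrajectoryTable:
    """Hand-built trajectory table from per-participant position lists."""
    rows = []
    for pid, pts in positions.items():
        for i, (x, y) in enumerate(pts):
            rows.append({"trial_id": "t0", "participant_id": pid,
                         "t": i * dt, "x": x, "y": y, "heading": 0.0,
                         "informed": False})
    return ca.TrajectoryTable(pd.DataFrame(rows), config)


@pytest.fixture
def hand_table_factory():
    return make_table
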