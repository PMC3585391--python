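"""Shared fixtures.

The simulation-outcome fixtures are session-scoped because zonal-model
replicates dominate the suite's runtime; every test that needs final-state
distributions draws from the same replicate pools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shoalstates.io import TrajectoryDataset, TrajectoryMeta, derive_kinematics
from shoalstates.sim import SimConfig, replicate_seed, run

#: One fixed "high" speed in the bistable band of the model's sweep range.
HIGH_SPEED = 3.0
LOW_SPEED = 0.1
REPLICATES = {30: 32, 70: 32, 150: 32, 300: 24}


@pytest.fixture(scope="session")
def high_speed_outcomes():
    """Final (O_p, O_r) of seeded replicates at the high speed, per N."""
    out = {}
    for n, reps in REPLICATES.items():
        rows = []
        for rep in range(reps):
            cfg = SimConfig(n=n, speed=HIGH_SPEED, seed=replicate_seed(2013, n, rep))
            o_p, o_r, _ = run(cfg)
            rows.append((min(o_p, 1.0), min(o_r, 1.0)))
        out[n] = np.array(rows)
    return out


@pytest.fixture(scope="session")
def low_speed_outcomes():
    """Final (O_p, O_r) at s = 0.1 for N = 150 (swarm regime check)."""
    rows = []
    for rep in range(24):
        cfg = SimConfig(n=150, speed=LOW_SPEED, seed=replicate_seed(31, 150, rep))
        o_p, o_r, _ = run(cfg)
        rows.append((min(o_p, 1.0), min(o_r, 1.0)))
    return np.array(rows)


@pytest.fixture()
def small_dataset():
    """2 frames x 3 fish, all moving, inside a 100 x 50 tank."""
    df = pd.DataFrame(
        {
            "frame": [0, 0, 0, 1, 1, 1],
            "id": [1, 2, 3, 1, 2, 3],
            "x": [10.0, 20.0, 30.0, 11.0, 21.0, 31.0],
            "y": [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
            "vx": [3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
            "vy": [4.0, 4.0, 4.0, 4.0, 4.0, 4.0],
        }
    )
    meta = TrajectoryMeta(fps=30, tank_width=100, tank_height=50)
    return TrajectoryDataset(df, meta)


@pytest.fixture()
def kinematic_dataset(small_dataset):
    return derive_kinematics(small_dataset)
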