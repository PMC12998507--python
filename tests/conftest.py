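"""Shared fixtures: one seeded synthetic landscape reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from peatfire.pipeline import map_burned_area
from peatfire.synthetic import SimConfig, simulate_scenes


@pytest.fixture(scope="session")
def cfg() -> SimConfig:
    return SimConfig(grid_height=128, grid_width=128, years=3, rng_seed=7)


@pytest.fixture(scope="session")
def sim(cfg):
    """(stacks, truth) of the session landscape."""
    return simulate_scenes(cfg)


@pytest.fixture(scope="session")
def ba_result(cfg, sim):
    stacks, truth = sim
    return map_burned_area(cfg, stacks, truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
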