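"""Shared fixtures: small simulated collections and toy cells."""

from __future__ import annotations

import numpy as np
import pytest

from micromerge.datasets import concat_observations
from micromerge.simulate import SimulationConfig, simulate_collection
from micromerge.symmetry import SpaceGroup, UnitCell


@pytest.fixture(scope="session")
def small_collection():
    """10 clean crystals, default noise — reused by several suites."""
    cfg = SimulationConfig(n_crystals=10, seed=101)
    datasets, truth = simulate_collection(cfg)
    return cfg, datasets, truth


@pytest.fixture(scope="session")
def small_pool(small_collection):
    cfg, datasets, truth = small_collection
    obs = concat_observations(datasets)
    cells = {ds.crystal_id: ds.cell for ds in datasets}
    return cfg, obs, cells, truth


@pytest.fixture
def toy_cell():
    return UnitCell(20.0, 25.0, 30.0)


@pytest.fixture
def p212121():
    return SpaceGroup("P212121")


def gauge_project(values: dict[str, float], kind: str) -> dict[str, float]:
    """Project true (k, B) onto the fitted gauge for comparison."""
    arr = np.array(list(values.values()))
    if kind == "k":
        shift = np.exp(np.mean(np.log(arr)))
        return {c: v / shift for c, v in values.items()}
    return {c: v - arr.mean() for c, v in values.items()}
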