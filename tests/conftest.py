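"""Shared fixtures: synthetic datasets are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bindkin.discretize import BinGrid
from bindkin.synthdata import (
    LangevinParams,
    child_seed,
    make_umbrella_set,
    preset,
    simulate_langevin,
)

KT = 0.6163


@pytest.fixture(scope="session")
def kt() -> float:
    return KT


@pytest.fixture(scope="session")
def double_well_umbrella_data():
    """Umbrella windows + one unbiased run on the 8 kT double well.

    Smaller than the headline reproduction run (20k steps per window) but
    enough for the estimator tests that use it.
    """
    pot = preset("double_well_8kT")
    par = LangevinParams(diffusion=10.0, dt=0.001, n_steps=20_000, seed=42,
                         initial_z=5.0)
    trajs = make_umbrella_set(pot, np.arange(1.0, 19.5, 2.0), 1.0, par)
    trajs.append(simulate_langevin(pot, par))
    grid = BinGrid.from_width(0.0, 20.0, 0.5)
    return pot, trajs, grid


@pytest.fixture(scope="session")
def funnel_unbiased_data():
    """Repeated unbiased binding/unbinding runs on the shallow funnel."""
    pot = preset("shallow_funnel")
    trajs = [
        simulate_langevin(
            pot,
            LangevinParams(diffusion=10.0, dt=0.005, n_steps=100_000,
                           seed=child_seed(7, i), initial_z=10.0),
        )
        for i in range(8)
    ]
    grid = BinGrid.from_width(5.0, 25.0, 0.5)
    return pot, trajs, grid
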