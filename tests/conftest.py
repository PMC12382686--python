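"""Shared fixtures: the two laboratory parameterisations and a cheap column.

The "fast" fixtures use a short, coarser column so forward runs take a
fraction of a second; the physics (sharp wetting front under ponding) is the
same as in the full-size cases.
"""

import numpy as np
import pytest

from soilcolumn.hydraulics import SoilHydraulicModel
from soilcolumn.presets import case_preset
from soilcolumn.richards import ColumnSpec, TimeGrid, solve_richards


@pytest.fixture(scope="session")
def c1():
    """Pure-gentamicin case preset (Ks=0.9481 cm/h, psi_d=92.8674 cm)."""
    return case_preset("pure")


@pytest.fixture(scope="session")
def c2():
    """Gentamicin-sulfate case preset (Ks=1.4689 cm/h, psi_d=47.0628 cm)."""
    return case_preset("sulfate")


@pytest.fixture(scope="session")
def model_c1(c1):
    return c1.model


@pytest.fixture(scope="session")
def fast_model(model_c1) -> SoilHydraulicModel:
    """c1 constitutive parameters, reused for the cheap column."""
    return model_c1


@pytest.fixture(scope="session")
def fast_column() -> ColumnSpec:
    return ColumnSpec(length=4.0, ponded_head=3.5, theta_initial=0.20, dz=0.1)


@pytest.fixture(scope="session")
def fast_grid() -> TimeGrid:
    return TimeGrid(dt=2e-3, t_end=0.15, dt_init=1e-6, save_interval=2e-3)


@pytest.fixture(scope="session")
def fast_flow(fast_column, fast_model, fast_grid):
    """A solved short infiltration run shared across tests."""
    return solve_richards(fast_column, fast_model, fast_grid)


@pytest.fixture(scope="session")
def c1_flow(c1):
    """Full-size c1 infiltration run, solved once for the session."""
    grid = TimeGrid(dt=2e-3, t_end=0.3, dt_init=1e-6, save_interval=2e-3)
    return solve_richards(c1.column, c1.model, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
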