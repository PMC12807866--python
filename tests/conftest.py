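import numpy as np
import pytest

from lumenmorph import cell_cycle as cc
from lumenmorph import sim_core as sc


@pytest.fixture(scope="session")
def small_grid():
    """96² lattice: enough room for a handful of cells, fast to relax."""
    return sc.GridSpec(nx=96, ny=96)


@pytest.fixture(scope="session")
def default_params():
    return sc.EnergyParams()


@pytest.fixture()
def single_cell_state(small_grid, default_params):
    return sc.init_state(small_grid, 1, seed=0, params=default_params)


@pytest.fixture()
def two_cell_lumen_state(small_grid, default_params):
    """Two cells with a freshly seeded micro-lumen in their cleft."""
    st = sc.init_state(small_grid, 2, seed=7, params=default_params)
    centre = sc._fields_centroid(st, small_grid)
    cc.seed_micro_lumen(st, small_grid, default_params, centre, 0.7)
    return st


def make_shell_state(grid, params, n_shell=8, lumen_area=2.0, seed=0):
    """Non-dividing cell shell with a central lumen seed (test substrate)."""
    st = sc.init_state(grid, n_shell, seed, params=params)
    centre = (grid.nx * grid.dx / 2.0, grid.ny * grid.dx / 2.0)
    cc.seed_micro_lumen(st, grid, params, centre, lumen_area)
    return st


@pytest.fixture(scope="session")
def relaxed_single_cell(small_grid, default_params):
    """A cell relaxed to its target volume (session-cached, read-only)."""
    st = sc.init_state(small_grid, 1, seed=1, params=default_params)
    st.target_volumes[:] = 2.0
    sc._advance(st, default_params, small_grid, 1500)
    return st


def assert_states_equal(a: sc.SimState, b: sc.SimState):
    np.testing.assert_array_equal(a.fields, b.fields)
    np.testing.assert_array_equal(a.lumen_field, b.lumen_field)
    np.testing.assert_array_equal(a.volumes, b.volumes)
    np.testing.assert_array_equal(a.target_volumes, b.target_volumes)
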