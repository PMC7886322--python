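"""Shared fixtures: small verification meshes and the cached model sweeps."""
from __future__ import annotations

import warnings

import pytest

from subtendon import (InterfaceModel, LoadCase, SubTendonID, box_bar_mesh,
                       default_material_map, load_table1, loft_mesh,
                       make_archetype, neo_hookean_from_modulus, solve_static)

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def materials():
    return default_material_map()


@pytest.fixture(scope="session")
def bar_mesh():
    """4 x 4 x 40 mm single-material bar (exact area 16 mm^2)."""
    return box_bar_mesh(4.0, 4.0, 40.0, 2.0)


@pytest.fixture(scope="session")
def bar_materials():
    return {SubTendonID.SOL: neo_hookean_from_modulus(100.0, 0.3)}


@pytest.fixture(scope="session")
def coarse_model3_mesh():
    """Archetype 3 meshed coarsely; shared across interface tests."""
    return loft_mesh(make_archetype(3), 3.0)


@pytest.fixture(scope="session")
def model3_sol_loaded(coarse_model3_mesh, materials):
    """One frictional solution on the coarse archetype-3 mesh."""
    lc = LoadCase(loaded={SubTendonID.SOL}, force_per_subtendon=100.0,
                  ramp_steps=3)
    return solve_static(coarse_model3_mesh, materials, lc,
                        InterfaceModel("frictional", mu=0.4))
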