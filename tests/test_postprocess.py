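"""Outcome measures: face averages, von Mises, summaries, rotation."""
import numpy as np
import pandas as pd
import pytest

from subtendon import (InterfaceModel, LoadCase, SubTendonID, box_bar_mesh,
                       face_rotation, mean_face_displacement,
                       neo_hookean_from_modulus, normalize_sweep, solve_static,
                       stress_summaries, von_mises_field)
from subtendon.fe import SolutionField


def fake_solution(mesh, u=None, cauchy=None):
    n, e = mesh.n_nodes, mesh.n_elements
    return SolutionField(
        mesh=mesh,
        u=np.zeros((n, 3)) if u is None else u,
        cauchy=np.zeros((e, 3, 3)) if cauchy is None else cauchy,
        interface_normal_force=np.zeros(0),
        interface_tangential_force=np.zeros((0, 2)),
        interface_slip=np.zeros(0, dtype=bool),
        reactions=np.zeros((n, 3)),
        external=np.zeros((n, 3)),
    )


@pytest.fixture(scope="module")
def unit_mesh():
    return box_bar_mesh(1.0, 1.0, 1.0, 0.5)


def test_mean_face_displacement_cases(unit_mesh):
    faces = unit_mesh.face_sets["proximal_SOL"]
    n = unit_mesh.n_nodes
    # rigid 1 mm z translation
    u = np.zeros((n, 3)); u[:, 2] = 1.0
    assert mean_face_displacement(fake_solution(unit_mesh, u), faces) == \
        pytest.approx(1.0)
    # pure transverse translation
    u = np.zeros((n, 3)); u[:, 0] = 3.0
    assert mean_face_displacement(fake_solution(unit_mesh, u), faces) == \
        pytest.approx(0.0)
    # linear ramp u_z = x over the unit face averages to 1/2
    u = np.zeros((n, 3)); u[:, 2] = unit_mesh.nodes[:, 0]
    assert mean_face_displacement(fake_solution(unit_mesh, u), faces) == \
        pytest.approx(0.5)
    with pytest.raises(ValueError):
        mean_face_displacement(fake_solution(unit_mesh), np.zeros((0, 6)))


def test_von_mises_closed_forms(unit_mesh):
    e = unit_mesh.n_elements
    cauchy = np.zeros((e, 3, 3))
    cauchy[0] = 5.0 * np.eye(3)                      # hydrostatic
    cauchy[1] = np.diag([7.0, 0.0, 0.0])             # uniaxial
    cauchy[2] = np.array([[0, 3.0, 0], [3.0, 0, 0], [0, 0, 0]])  # pure shear
    vm = von_mises_field(fake_solution(unit_mesh, cauchy=cauchy))
    assert vm[0] == pytest.approx(0.0, abs=1e-12)
    assert vm[1] == pytest.approx(7.0)
    assert vm[2] == pytest.approx(3.0 * np.sqrt(3.0))


def test_stress_summaries_uniform_block(unit_mesh):
    e = unit_mesh.n_elements
    cauchy = np.tile(np.diag([0.0, 0.0, 4.0]), (e, 1, 1))
    mean_vm, peak_vm, rec = stress_summaries(
        fake_solution(unit_mesh, cauchy=cauchy), unit_mesh,
        exclusion_layers=0)
    assert mean_vm == pytest.approx(4.0)
    assert peak_vm == pytest.approx(4.0)
    assert rec["region"] in {"anterior", "posterior", "lateral", "medial",
                             "internal"}


def test_stress_summaries_exclusion_guard(unit_mesh):
    sol = fake_solution(unit_mesh)
    with pytest.raises(ValueError):
        stress_summaries(sol, unit_mesh, exclusion_layers=50)


def test_two_material_bar_in_series():
    """Equal cross-sections in series carry the same stress (within 1%)."""
    mats = {SubTendonID.SOL: neo_hookean_from_modulus(100.0, 0.3)}
    mesh = box_bar_mesh(4.0, 4.0, 40.0, 2.0)
    lc = LoadCase(loaded={SubTendonID.SOL}, force_per_subtendon=2.0,
                  ramp_steps=1, distal_constraint="roller")
    sol = solve_static(mesh, mats, lc, InterfaceModel("bonded"))
    vm = von_mises_field(sol)
    assert vm.std() / vm.mean() < 0.01
    mean_vm, peak_vm, _ = stress_summaries(sol, mesh, exclusion_layers=0)
    assert peak_vm >= mean_vm


def test_face_rotation_recovery(unit_mesh):
    faces = unit_mesh.face_sets["proximal_SOL"]
    ids = np.unique(faces)
    nodes = unit_mesh.nodes
    n = unit_mesh.n_nodes
    theta = np.radians(5.0)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    centre = nodes[ids, :2].mean(axis=0)
    u = np.zeros((n, 3))
    u[:, :2] = (nodes[:, :2] - centre) @ R.T - (nodes[:, :2] - centre)
    assert face_rotation(fake_solution(unit_mesh, u), faces) == \
        pytest.approx(5.0, abs=0.01)
    # pure translation reads as zero rotation
    u = np.zeros((n, 3)); u[:, 0] = 2.0
    assert face_rotation(fake_solution(unit_mesh, u), faces) == \
        pytest.approx(0.0, abs=1e-9)


def test_face_rotation_with_noise(unit_mesh):
    faces = unit_mesh.face_sets["proximal_SOL"]
    ids = np.unique(faces)
    nodes = unit_mesh.nodes
    n = unit_mesh.n_nodes
    rng = np.random.default_rng(11)
    theta = np.radians(5.0)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    centre = nodes[ids, :2].mean(axis=0)
    radius = np.linalg.norm(nodes[ids, :2] - centre, axis=1).mean()
    errs = []
    for _ in range(50):
        u = np.zeros((n, 3))
        u[:, :2] = (nodes[:, :2] - centre) @ R.T - (nodes[:, :2] - centre)
        u[ids, :2] += rng.normal(0, 0.01 * radius, (len(ids), 2))
        errs.append(face_rotation(fake_solution(unit_mesh, u), faces) - 5.0)
    assert np.max(np.abs(errs)) < 0.5


def test_normalize_sweep_properties():
    base = pd.DataFrame({
        "model_id": 3, "loaded": "SOL",
        "interface": ["frictionless", "frictional_mu0.4", "bonded"],
        "mu": [0.0, 0.4, np.nan],
        "sol_face_displacement_mm": [2.0, 1.0, 0.5],
        "mean_vm_mpa": [4.0, 3.0, 2.0],
    })
    out = normalize_sweep(base)
    assert out.loc[0, "normalized_displacement"] == 1.0
    assert out.loc[1, "normalized_displacement"] == pytest.approx(0.5)
    assert out.loc[0, "mean_vm_normalized"] == 1.0
    # scale invariance of the ratio
    scaled = base.copy()
    scaled["sol_face_displacement_mm"] *= 7.0
    assert np.allclose(normalize_sweep(scaled)["normalized_displacement"],
                       out["normalized_displacement"])
    # missing frictionless reference
    with pytest.raises(ValueError):
        normalize_sweep(base[base.interface != "frictionless"])
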