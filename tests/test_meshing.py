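"""Lofted TET10 meshing: conformity, interface pairs, volumes, convergence."""
import numpy as np
import pytest

from subtendon import (LoadCase, SubTendonID, box_bar_mesh, converge_mesh,
                       loft_mesh, make_archetype, merge_interfaces,
                       neo_hookean_from_modulus)
from subtendon.meshing import PAIR_TOL
from subtendon.vtkio import read_vtu, write_vtu


@pytest.fixture(scope="module")
def mesh3():
    return loft_mesh(make_archetype(3), 2.8)


def test_positive_jacobians_and_labels(mesh3):
    assert mesh3.n_elements > 0
    assert mesh3.element_volumes().min() > 0
    # element labels partition the mesh across all three sub-tendons
    assert set(np.unique(mesh3.elem_label)) == {0, 1, 2}


def test_edge_length_bound(mesh3):
    assert mesh3.max_edge_length() <= 1.5 * mesh3.h


def test_prism_volume_refinement():
    """Zero-twist loft reproduces the exact prism volume at any h."""
    g = make_archetype(2, overrides={"twist_deg": 0.0})
    v1 = loft_mesh(g, 3.0).volume()
    v2 = loft_mesh(g, 1.5).volume()
    exact = 90.4 * 40.0
    assert abs(v1 - v2) / v2 < 0.005
    assert v1 == pytest.approx(exact, rel=1e-6)


def test_twisted_volume_close_to_prismatic(mesh3):
    assert mesh3.volume() == pytest.approx(42.3 * 40.0, rel=0.01)


def test_interface_pairs_coincide_and_orthonormal(mesh3):
    gap = np.linalg.norm(mesh3.nodes[mesh3.pair_a] - mesh3.nodes[mesh3.pair_b],
                         axis=1)
    assert len(gap) > 0
    assert gap.max() <= PAIR_TOL
    R = mesh3.pair_frames
    assert np.allclose(np.einsum("pij,pkj->pik", R, R), np.eye(3), atol=1e-9)
    # pairing spans different owners and is unique per unordered pair
    assert np.all(mesh3.node_owner[mesh3.pair_a]
                  != mesh3.node_owner[mesh3.pair_b])
    keys = {tuple(sorted((int(a), int(b))))
            for a, b in zip(mesh3.pair_a, mesh3.pair_b)}
    assert len(keys) == len(mesh3.pair_a)


def test_interface_pairing_complete(mesh3):
    """Every node on an interface face has a coincident partner."""
    faces = mesh3.face_sets["interface"]
    paired = set(mesh3.pair_a.tolist()) | set(mesh3.pair_b.tolist())
    assert set(np.unique(faces)).issubset(paired)


def test_merged_mesh_volume_and_no_pairs(mesh3):
    merged = merge_interfaces(mesh3)
    assert merged.volume() == pytest.approx(mesh3.volume(), rel=1e-12)
    assert merged.n_nodes < mesh3.n_nodes
    assert len(merged.pair_a) == 0


def test_box_bar_exact_volume():
    m = box_bar_mesh(4.0, 4.0, 40.0, 2.0)
    assert m.volume() == pytest.approx(640.0, rel=1e-9)
    assert len(m.face_sets["distal_SOL"]) > 0
    assert len(m.face_sets["proximal_SOL"]) > 0


def test_mesh_convergence_bar_matches_bar_theory():
    """Converged tip displacement is within 2% of FL/(EA) at small load.

    Equal sub-tendon area fractions under equal loads give a uniform
    traction, so the untwisted composite behaves as a single linear bar.
    """
    E = 100.0
    fr = {s: 1 / 3 for s in SubTendonID}
    g = make_archetype(2, overrides={"twist_deg": 0.0, "fractions": fr})
    mats = {s: neo_hookean_from_modulus(E, 0.3) for s in SubTendonID}
    load = LoadCase(loaded=set(SubTendonID), force_per_subtendon=1.0,
                    ramp_steps=1, distal_constraint="roller")
    h, table = converge_mesh(g, mats, load, criterion=0.02,
                             refinement_factor=1.4, h0=6.0,
                             max_refinements=4)
    exact = 3.0 * 40.0 / (E * 90.4)
    assert table["monitored_mm"].iloc[-1] == pytest.approx(exact, rel=0.02)
    assert h in table["max_edge_length"].values
    assert table["rel_change"].iloc[-1] < 0.02


def test_mesh_convergence_loose_criterion_stops_immediately():
    g = make_archetype(2, overrides={"twist_deg": 0.0})
    mats = {s: neo_hookean_from_modulus(100.0, 0.3) for s in SubTendonID}
    load = LoadCase(loaded=set(SubTendonID), force_per_subtendon=1.0,
                    ramp_steps=1)
    h, table = converge_mesh(g, mats, load, criterion=1.0, h0=6.0)
    assert len(table) == 2  # first refinement pair satisfies a 100% criterion
    assert h == pytest.approx(6.0)


def test_vtu_roundtrip(tmp_path, mesh3):
    path = tmp_path / "mesh.vtu"
    write_vtu(mesh3, path)
    back = read_vtu(path)
    assert np.allclose(back.nodes, mesh3.nodes)
    assert np.array_equal(back.elements, mesh3.elements)
    assert np.array_equal(back.pair_a, mesh3.pair_a)
    assert np.allclose(back.pair_area, mesh3.pair_area)
    assert set(back.face_sets) == set(mesh3.face_sets)


def test_invalid_edge_length():
    with pytest.raises(ValueError):
        loft_mesh(make_archetype(3), -1.0)
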