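"""Outcome measures computed from FE solutions.

The displacement outcome is the area-weighted mean longitudinal displacement
of the proximal soleus face; displacement and mean von Mises stress are
normalised within each (model, load) group to the frictionless solution; the
stress outcomes are the volume-weighted mean and the peak centroid von Mises
stress with its location (owning sub-tendon and surface region).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SUBTENDON_ORDER
from .fe import SolutionField
from .meshing import TendonMesh, _face_geometry

__all__ = [
    "mean_face_displacement",
    "von_mises_field",
    "stress_summaries",
    "face_rotation",
    "sweep_table",
    "normalize_sweep",
]


def _face_node_weights(mesh_nodes: np.ndarray, faces6: np.ndarray):
    """Lumped tributary areas of the nodes of a 6-node-triangle face set."""
    weights: dict[int, float] = {}
    for f in faces6:
        c0, c1, c2, m01, m12, m02 = f
        p = mesh_nodes[[c0, c1, c2, m01, m12, m02]]
        subtris = ((0, 3, 5), (1, 4, 3), (2, 5, 4), (3, 4, 5))
        for st in subtris:
            q = p[list(st)]
            a3 = 0.5 * np.linalg.norm(np.cross(q[1] - q[0], q[2] - q[0])) / 3.0
            for li in st:
                weights[int(f[li])] = weights.get(int(f[li]), 0.0) + a3
    ids = np.fromiter(weights.keys(), dtype=np.int64)
    w = np.fromiter(weights.values(), dtype=float)
    return ids, w


def mean_face_displacement(solution: SolutionField, faces6: np.ndarray,
                           component: int = 2) -> float:
    """Area-weighted mean displacement component over a boundary face set."""
    if faces6 is None or len(faces6) == 0:
        raise ValueError("empty face set")
    ids, w = _face_node_weights(solution.mesh.nodes, faces6)
    return float(np.average(solution.u[ids, component], weights=w))


def von_mises_field(solution: SolutionField) -> np.ndarray:
    """Per-element centroid von Mises stress (MPa)."""
    s = solution.cauchy
    tr = np.trace(s, axis1=-2, axis2=-1)
    dev = s - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def _distal_ring_exclusion(mesh: TendonMesh, layers: int) -> np.ndarray:
    """Mask of elements within ``layers`` node-sharing rings of the distal face."""
    excluded = np.zeros(mesh.n_elements, dtype=bool)
    if layers <= 0:
        return excluded
    seed_nodes = set()
    for s in SUBTENDON_ORDER:
        faces = mesh.face_sets.get(f"distal_{s.value}")
        if faces is not None and len(faces):
            seed_nodes.update(faces.ravel().tolist())
    frontier = np.array(sorted(seed_nodes), dtype=np.int64)
    touched_nodes = np.zeros(mesh.n_nodes, dtype=bool)
    touched_nodes[frontier] = True
    for _ in range(layers):
        hit = np.any(touched_nodes[mesh.elements], axis=1) & ~excluded
        excluded |= hit
        touched_nodes[np.unique(mesh.elements[hit])] = True
    return excluded


def _classify_region(mesh: TendonMesh, point: np.ndarray) -> str:
    """Surface region of a point: nearest boundary face wins.

    Interface-adjacent peaks are labelled ``internal``; exterior peaks take
    the dominant axis of the nearest exterior face's outward normal
    (+y posterior, -y anterior, +x lateral, -x medial).  Ties break toward
    ``internal``.
    """
    ext = mesh.face_sets.get("exterior")
    ifc = mesh.face_sets.get("interface")
    d_ext = d_ifc = np.inf
    n_ext = None
    if ext is not None and len(ext):
        areas, normals, centroids = _face_geometry(mesh.nodes, ext)
        dist = np.linalg.norm(centroids - point, axis=1)
        i = int(np.argmin(dist))
        d_ext, n_ext = dist[i], normals[i]
    if ifc is not None and len(ifc):
        _, _, centroids = _face_geometry(mesh.nodes, ifc)
        d_ifc = float(np.linalg.norm(centroids - point, axis=1).min())
    if d_ifc <= d_ext or n_ext is None:
        return "internal"
    nx, ny = n_ext[0], n_ext[1]
    if abs(nx) > abs(ny):
        return "lateral" if nx > 0 else "medial"
    if abs(ny) > abs(nx):
        return "posterior" if ny > 0 else "anterior"
    return "internal"


def stress_summaries(solution: SolutionField, mesh: TendonMesh | None = None,
                     exclusion_layers: int = 1, volume_weighted: bool = True):
    """Mean and peak von Mises stress plus the peak location record.

    The mean is the (by default volume-weighted) element average over the
    whole mesh; the peak is taken over elements at least ``exclusion_layers``
    element rings away from the fixed distal face, where the full clamp
    creates a discretisation stress artefact.
    """
    mesh = mesh or solution.mesh
    vm = von_mises_field(solution)
    vols = mesh.element_volumes()
    mean_vm = float(np.average(vm, weights=vols if volume_weighted else None))
    excluded = _distal_ring_exclusion(mesh, exclusion_layers)
    if excluded.all():
        raise ValueError("all elements excluded from the peak search")
    vm_search = np.where(excluded, -np.inf, vm)
    ie = int(np.argmax(vm_search))
    centroid = mesh.nodes[mesh.elements[ie, :4]].mean(axis=0)
    record = {
        "element": ie,
        "coords_mm": centroid,
        "sub_tendon": SUBTENDON_ORDER[mesh.elem_label[ie]],
        "region": _classify_region(mesh, centroid),
    }
    return mean_vm, float(vm[ie]), record


def face_rotation(solution: SolutionField, faces6: np.ndarray) -> float:
    """Best-fit rigid rotation (degrees) of a face about the z axis.

    Least-squares orthogonal fit in the transverse plane: with reference
    positions p and displaced positions q (both relative to their centroids),
    the optimal angle is atan2(sum p x q, sum p . q).
    """
    if faces6 is None or len(faces6) == 0:
        raise ValueError("empty face set")
    ids = np.unique(faces6.ravel())
    p = solution.mesh.nodes[ids, :2]
    q = p + solution.u[ids, :2]
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    if np.linalg.matrix_rank(np.column_stack([p, np.ones(len(p))])) < 3:
        raise ValueError("face nodes are collinear")
    cross = float(np.sum(p[:, 0] * q[:, 1] - p[:, 1] * q[:, 0]))
    dot = float(np.sum(p * q))
    return float(np.degrees(np.arctan2(cross, dot)))


# ---------------------------------------------------------------------------
# sweep tables
# ---------------------------------------------------------------------------

def sweep_table(solutions: dict, model_id, mesh: TendonMesh,
                exclusion_layers: int = 1) -> pd.DataFrame:
    """Tidy outcome table from ``run_load_cases`` output.

    One row per (interface, load case): soleus-face displacement, mean and
    peak von Mises stress, peak location and proximal-soleus face rotation.
    Normalised columns are filled by :func:`normalize_sweep`.
    """
    sol_face = mesh.face_sets["proximal_SOL"]
    rows = []
    for (iface_label, load_label), sol in solutions.items():
        mean_vm, peak_vm, rec = stress_summaries(
            sol, mesh, exclusion_layers=exclusion_layers)
        mu = np.nan
        if iface_label.startswith("frictional_mu"):
            mu = float(iface_label.removeprefix("frictional_mu"))
        elif iface_label == "frictionless":
            mu = 0.0
        rows.append({
            "model_id": model_id,
            "interface": iface_label,
            "mu": mu,
            "loaded": load_label,
            "sol_face_displacement_mm": mean_face_displacement(sol, sol_face),
            "mean_vm_mpa": mean_vm,
            "peak_vm_mpa": peak_vm,
            "peak_x_mm": rec["coords_mm"][0],
            "peak_y_mm": rec["coords_mm"][1],
            "peak_z_mm": rec["coords_mm"][2],
            "peak_sub_tendon": str(rec["sub_tendon"]),
            "peak_region": rec["region"],
            "sol_face_rotation_deg": face_rotation(sol, sol_face),
        })
    return normalize_sweep(pd.DataFrame(rows))


def normalize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Add columns normalised to the frictionless row per (model, load) group.

    ``normalized_displacement`` and ``mean_vm_normalized`` are exactly 1 on
    the frictionless rows by construction.
    """
    df = table.copy()
    for col_src, col_dst in (
        ("sol_face_displacement_mm", "normalized_displacement"),
        ("mean_vm_mpa", "mean_vm_normalized"),
    ):
        out = np.full(len(df), np.nan)
        for (_, _), grp in df.groupby(["model_id", "loaded"], sort=False):
            ref_rows = grp[grp["interface"] == "frictionless"]
            if len(ref_rows) != 1:
                raise ValueError("each (model, load) group needs exactly one "
                                 "frictionless reference row")
            ref = float(ref_rows[col_src].iloc[0])
            if ref == 0.0:
                raise ValueError("zero frictionless reference value")
            out[grp.index] = grp[col_src] / ref
        df[col_dst] = out
    return df
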