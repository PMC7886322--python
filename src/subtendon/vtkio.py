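"""Minimal ASCII VTU (VTK XML UnstructuredGrid) export and import.

Writes TET10 meshes (VTK cell type 24, whose edge-node ordering matches the
package's local ordering) with the sub-tendon element labels, optional nodal
and element fields, and the face-set / interface-pair metadata as FieldData
arrays, so a mesh round-trips through a single self-contained file readable
by any VTK-based viewer.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .meshing import TendonMesh

__all__ = ["write_vtu", "read_vtu", "write_solution_vtu"]

VTK_QUADRATIC_TETRA = 24


def _array_text(a: np.ndarray) -> str:
    flat = np.asarray(a).ravel()
    if flat.dtype.kind == "f":
        return " ".join(f"{v:.17g}" for v in flat)
    return " ".join(str(int(v)) for v in flat)


def _data_array(parent, name, a, ncomp=None):
    a = np.asarray(a)
    vtype = "Float64" if a.dtype.kind == "f" else "Int64"
    el = ET.SubElement(parent, "DataArray", {
        "type": vtype, "Name": name, "format": "ascii",
    })
    if ncomp:
        el.set("NumberOfComponents", str(ncomp))
    el.text = _array_text(a)
    return el


def write_vtu(mesh: TendonMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write a mesh (plus optional fields) as an ASCII .vtu file."""
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    root = ET.Element("VTKFile", {
        "type": "UnstructuredGrid", "version": "0.1",
        "byte_order": "LittleEndian",
    })
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(ug, "Piece", {
        "NumberOfPoints": str(n_pts), "NumberOfCells": str(n_cells),
    })
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", mesh.nodes.astype(float), ncomp=3)

    cells = ET.SubElement(piece, "Cells")
    _data_array(cells, "connectivity", mesh.elements.astype(np.int64))
    _data_array(cells, "offsets", 10 * np.arange(1, n_cells + 1))
    _data_array(cells, "types",
                np.full(n_cells, VTK_QUADRATIC_TETRA, dtype=np.int64))

    cd = ET.SubElement(piece, "CellData")
    _data_array(cd, "sub_tendon", mesh.elem_label.astype(np.int64))
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr)
        ncomp = arr.size // n_cells
        _data_array(cd, name, arr, ncomp=ncomp if ncomp > 1 else None)

    pd_el = ET.SubElement(piece, "PointData")
    _data_array(pd_el, "node_owner", mesh.node_owner.astype(np.int64))
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr)
        ncomp = arr.size // n_pts
        _data_array(pd_el, name, arr, ncomp=ncomp if ncomp > 1 else None)

    fd = ET.SubElement(ug, "FieldData")
    for name, faces in mesh.face_sets.items():
        _data_array(fd, f"faceset:{name}", np.asarray(faces, np.int64))
    if len(mesh.pair_a):
        _data_array(fd, "pairs:a", mesh.pair_a)
        _data_array(fd, "pairs:b", mesh.pair_b)
        _data_array(fd, "pairs:frames", mesh.pair_frames.astype(float))
        _data_array(fd, "pairs:area", mesh.pair_area.astype(float))
    _data_array(fd, "meta:h", np.array([mesh.h], dtype=float))

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")


def write_solution_vtu(solution, path) -> None:
    """Export a solution: displacement vector, Cauchy tensor, von Mises."""
    from .postprocess import von_mises_field

    mesh = solution.mesh
    write_vtu(
        mesh, path,
        point_data={"displacement": solution.u},
        cell_data={
            "cauchy": solution.cauchy.reshape(mesh.n_elements, 9),
            "von_mises": von_mises_field(solution),
        },
    )


def _parse_array(el, dtype) -> np.ndarray:
    txt = (el.text or "").split()
    return np.asarray(txt, dtype=dtype)


def read_vtu(path) -> TendonMesh:
    """Read a mesh written by :func:`write_vtu` back into a TendonMesh."""
    root = ET.parse(path).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError("not an UnstructuredGrid VTU file")
    arrays = {}
    for da in piece.iter("DataArray"):
        arrays[da.get("Name")] = da
    nodes = _parse_array(arrays["Points"], float).reshape(-1, 3)
    conn = _parse_array(arrays["connectivity"], np.int64)
    types = _parse_array(arrays["types"], np.int64)
    if not np.all(types == VTK_QUADRATIC_TETRA):
        raise ValueError("only quadratic tetrahedral meshes are supported")
    elements = conn.reshape(-1, 10)
    labels = _parse_array(arrays["sub_tendon"], np.int64).astype(np.int8)
    owner = _parse_array(arrays["node_owner"], np.int64).astype(np.int8)

    face_sets = {}
    pair_a = pair_b = np.zeros(0, np.int64)
    frames = np.zeros((0, 3, 3))
    area = np.zeros(0)
    h = float("nan")
    fd = root.find("./UnstructuredGrid/FieldData")
    if fd is not None:
        for da in fd.iter("DataArray"):
            name = da.get("Name", "")
            if name.startswith("faceset:"):
                face_sets[name.removeprefix("faceset:")] = \
                    _parse_array(da, np.int64).reshape(-1, 6)
            elif name == "pairs:a":
                pair_a = _parse_array(da, np.int64)
            elif name == "pairs:b":
                pair_b = _parse_array(da, np.int64)
            elif name == "pairs:frames":
                frames = _parse_array(da, float).reshape(-1, 3, 3)
            elif name == "pairs:area":
                area = _parse_array(da, float)
            elif name == "meta:h":
                h = float(_parse_array(da, float)[0])
    mesh = TendonMesh(
        nodes=nodes, elements=elements, elem_label=labels,
        face_sets=face_sets, pair_a=pair_a, pair_b=pair_b,
        pair_frames=frames, pair_area=area, node_owner=owner, h=h,
        meta={"source": str(path)},
    )
    mesh.validate()
    return mesh
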