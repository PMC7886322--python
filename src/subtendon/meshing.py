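"""Lofted quadratic tetrahedral meshing of the parametric sub-tendon geometry.

Each convex 2D partition of the elliptical section is triangulated with a
shared chord discretisation (so the three partitions conform along their
interfaces), the triangulation is extruded layer by layer following the
twist, wedges are split into tetrahedra with a min-vertex diagonal rule that
keeps neighbouring wedges conforming, and elements are upgraded to 10-node
quadratic tetrahedra (TET10) with straight edges.

Interface handling: each sub-tendon owns private copies of the nodes on its
boundary with the neighbouring sub-tendons; coincident copies are recorded as
interface node pairs together with a local orthonormal frame (interface
normal n, longitudinal tangent t1, in-plane transverse tangent t2) and a
tributary area used by the penalty interface of the solver.  Collapsing all
pairs yields the conforming merged (fully bonded) mesh.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Point, Polygon

from .core import SUBTENDON_ORDER, SubTendonID
from .geometry import (
    TendonGeometry,
    PartitionParams,
    base_partition_polygons,
    rotation_2d,
)

__all__ = ["TendonMesh", "loft_mesh", "merge_interfaces", "box_bar_mesh",
           "converge_mesh"]

PAIR_TOL = 1e-6  # mm; reference-configuration coincidence tolerance

# local faces of a TET10, outward-oriented: (corner triple, midside triple)
_TET_FACES = (
    ((0, 2, 1), (6, 5, 4)),
    ((0, 1, 3), (4, 8, 7)),
    ((1, 2, 3), (5, 9, 8)),
    ((0, 3, 2), (7, 9, 6)),
)
# local edge -> corner pair for the TET10 midside nodes 4..9
_TET_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


@dataclass
class TendonMesh:
    """Labelled conforming TET10 mesh with interface node pairs.

    ``elements`` follow the usual TET10 local ordering (corners 0-3, then
    midsides on edges 01, 12, 02, 03, 13, 23).  ``face_sets`` maps names like
    ``"distal_SOL"``, ``"proximal_LG"``, ``"exterior"`` and ``"interface"``
    to (F, 6) arrays of 6-node boundary triangles.  ``pair_frames[p]`` holds
    the rows (n, t1, t2) of pair p's local frame.
    """

    nodes: np.ndarray
    elements: np.ndarray
    elem_label: np.ndarray  # index into SUBTENDON_ORDER
    face_sets: dict[str, np.ndarray]
    pair_a: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    pair_b: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    pair_frames: np.ndarray = field(default_factory=lambda: np.zeros((0, 3, 3)))
    pair_area: np.ndarray = field(default_factory=lambda: np.zeros(0))
    node_owner: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    h: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        """Reference volumes (elements are straight-edged, hence affine)."""
        X = self.nodes[self.elements[:, :4]]
        d = X[:, 1:] - X[:, :1]
        return np.linalg.det(d) / 6.0

    def volume(self) -> float:
        return float(self.element_volumes().sum())

    def max_edge_length(self) -> float:
        X = self.nodes[self.elements[:, :4]]
        m = 0.0
        for i, j in _TET_EDGES:
            m = max(m, float(np.linalg.norm(X[:, i] - X[:, j], axis=1).max()))
        return m

    def validate(self) -> None:
        vols = self.element_volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{int((vols <= 0).sum())} elements with "
                             "non-positive Jacobian")
        if len(self.pair_a):
            gap = np.linalg.norm(
                self.nodes[self.pair_a] - self.nodes[self.pair_b], axis=1)
            if gap.max() > PAIR_TOL:
                raise ValueError("interface pair nodes do not coincide")
            R = self.pair_frames
            ortho = np.einsum("pij,pkj->pik", R, R)
            if not np.allclose(ortho, np.eye(3), atol=1e-9):
                raise ValueError("interface frames are not orthonormal")

    def subtendon_faces(self, prefix: str) -> dict[SubTendonID, np.ndarray]:
        out = {}
        for s in SUBTENDON_ORDER:
            key = f"{prefix}_{s.value}"
            if key in self.face_sets and len(self.face_sets[key]):
                out[s] = self.face_sets[key]
        return out


# ---------------------------------------------------------------------------
# 2D section meshing
# ---------------------------------------------------------------------------

def _polyline(p, q, h):
    """Points from p to q (inclusive) at spacing <= h."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    n = max(int(math.ceil(np.linalg.norm(q - p) / h)), 1)
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return p * (1 - t) + q * t


def _arc_points(params: PartitionParams, th0: float, th1: float, h: float):
    """Ellipse arc sampled at approximately uniform arc length <= h.

    Interior arc points are pushed slightly outwards (sector-area preserving
    radial correction in the circle-mapped coordinates) so the polygonised
    section area converges to the analytic ellipse area at O(h^4) instead of
    the inscribed polygon's O(h^2) deficit.
    """
    a, b = params.a, params.b
    fine = np.linspace(th0, th1, 512)
    pts = np.column_stack([a * np.cos(fine), b * np.sin(fine)])
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    n = max(int(math.ceil(s[-1] / h)), 2)
    th = np.interp(np.linspace(0.0, s[-1], n + 1), s, fine)

    # In circle-mapped coordinates (x/a, y/b) the arc is a unit-circle arc;
    # the analytic area between the arc and its chord is (dth - sin dth)/2.
    # Solve a radial push gamma for the interior points so the polyline
    # reproduces that area exactly (endpoints stay on the chords).
    span = th1 - th0
    target = 0.5 * (span - math.sin(span))

    def seg_area(gamma):
        r = np.ones(n + 1)
        r[1:-1] = 1.0 + gamma
        x, y = r * np.cos(th), r * np.sin(th)
        return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    from scipy.optimize import brentq
    if seg_area(0.0) < target:
        gamma = brentq(lambda g: seg_area(g) - target, 0.0, 1.0, xtol=1e-14)
    else:  # pragma: no cover - already area-exact
        gamma = 0.0
    scale = np.ones(n + 1)
    scale[1:-1] = 1.0 + gamma
    return np.column_stack([a * scale * np.cos(th), b * scale * np.sin(th)])


class _PointRegistry:
    def __init__(self):
        self.points: list[np.ndarray] = []
        self._index: dict[tuple, int] = {}

    def add(self, p) -> int:
        key = (round(float(p[0]), 9), round(float(p[1]), 9))
        idx = self._index.get(key)
        if idx is None:
            idx = len(self.points)
            self._index[key] = idx
            self.points.append(np.asarray(p, float))
        return idx

    def add_chain(self, pts) -> list[int]:
        return [self.add(p) for p in pts]


@dataclass
class _Section2D:
    points: np.ndarray           # (N, 2) canonical (proximal) frame
    triangles: np.ndarray        # (M, 3)
    tri_label: np.ndarray        # (M,) index into SUBTENDON_ORDER
    membership: np.ndarray       # (N, 3) bool


def _interior_lattice(poly: Polygon, h: float, clearance: float) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    shrunk = poly.buffer(-clearance)
    if shrunk.is_empty:
        return np.zeros((0, 2))
    hh = 0.85 * h
    pts = []
    dy = hh * math.sqrt(3) / 2
    row = 0
    y = miny + 0.45 * hh
    while y < maxy:
        x = minx + (0.25 if row % 2 else 0.75) * hh
        while x < maxx:
            if shrunk.contains(Point(x, y)):
                pts.append((x, y))
            x += hh
        y += dy
        row += 1
    return np.asarray(pts) if pts else np.zeros((0, 2))


def _section_mesh_2d(params: PartitionParams, h: float) -> _Section2D:
    a, b, y0, x0 = params.a, params.b, params.y0, params.x0
    xa, yt = params.x_chord, params.y_top
    th_r = math.atan2(y0 / b, xa / a)
    th_l = math.pi - th_r
    th_t = math.atan2(yt / b, x0 / a)

    P_L, P_R = np.array([-xa, y0]), np.array([xa, y0])
    J, T = np.array([x0, y0]), np.array([x0, yt])

    reg = _PointRegistry()
    chordA_left = reg.add_chain(_polyline(P_L, J, h))
    chordA_right = reg.add_chain(_polyline(J, P_R, h))
    chordB = reg.add_chain(_polyline(J, T, h))
    arc_bottom = reg.add_chain(_arc_points(params, th_l - 2 * math.pi, th_r, h))
    arc_right = reg.add_chain(_arc_points(params, th_r, th_t, h))
    arc_left = reg.add_chain(_arc_points(params, th_t, th_l, h))

    boundary_ids = {
        SubTendonID.SOL: chordA_left + chordA_right + arc_bottom,
        SubTendonID.LG: chordA_right + arc_right + chordB,
        SubTendonID.MG: chordA_left + chordB + arc_left,
    }
    polys = base_partition_polygons(params, n_arc=96)

    tri_list, lab_list = [], []
    part_point_ids: dict[SubTendonID, list[int]] = {}
    for si, s in enumerate(SUBTENDON_ORDER):
        ids = sorted(set(boundary_ids[s]))
        poly = Polygon(polys[s])
        interior = _interior_lattice(poly, h, clearance=0.35 * h)
        for p in interior:
            ids.append(reg.add(p))
        part_point_ids[s] = ids
        pts = np.array([reg.points[i] for i in ids])
        if len(pts) < 3:
            raise ValueError(f"degenerate partition {s}: too few points")
        tri = Delaunay(pts)
        loc = tri.simplices
        # drop slivers from collinear boundary runs
        p0, p1, p2 = pts[loc[:, 0]], pts[loc[:, 1]], pts[loc[:, 2]]
        area2 = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - \
                (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1])
        keep = np.abs(area2) > 1e-10 * h * h
        loc = loc[keep]
        flip = area2[keep] < 0
        loc[flip] = loc[flip][:, ::-1]
        gids = np.asarray(ids, dtype=np.int64)
        tri_list.append(gids[loc])
        lab_list.append(np.full(len(loc), si, dtype=np.int8))

    points = np.asarray(reg.points)
    triangles = np.vstack(tri_list)
    labels = np.concatenate(lab_list)
    membership = np.zeros((len(points), 3), dtype=bool)
    for si, s in enumerate(SUBTENDON_ORDER):
        membership[np.asarray(part_point_ids[s], dtype=np.int64), si] = True
    return _Section2D(points, triangles, labels, membership)


# ---------------------------------------------------------------------------
# wedge splitting (min-vertex diagonal rule; conforming across wedges)
# ---------------------------------------------------------------------------

def _split_wedge(dec, out):
    """Split a wedge into 3 tets.

    ``dec`` are 6 canonical ids used for the diagonal decision (shared across
    sub-tendons so interface triangulations match); ``out`` are the ids to
    emit.  Bottom = indices 0-2, top = 3-5, with top[i] above bottom[i] and
    the canonical bottom ids smaller than the top ids.
    """
    r = int(np.argmin(dec[:3]))
    o = (r, (r + 1) % 3, (r + 2) % 3)
    d = [dec[o[0]], dec[o[1]], dec[o[2]], dec[3 + o[0]], dec[3 + o[1]], dec[3 + o[2]]]
    v = [out[o[0]], out[o[1]], out[o[2]], out[3 + o[0]], out[3 + o[1]], out[3 + o[2]]]
    if min(d[1], d[5]) < min(d[2], d[4]):
        return [(v[0], v[1], v[2], v[5]), (v[0], v[1], v[5], v[4]),
                (v[0], v[4], v[5], v[3])]
    return [(v[0], v[1], v[2], v[4]), (v[0], v[4], v[2], v[5]),
            (v[0], v[4], v[5], v[3])]


# ---------------------------------------------------------------------------
# lofting
# ---------------------------------------------------------------------------

def _quadratic_from_linear(nodes: np.ndarray, tets: np.ndarray):
    """Insert straight-edge midside nodes; returns (nodes10, elements10)."""
    edges = tets[:, _TET_EDGES].reshape(-1, 2)  # (E*6, 2)
    edges_sorted = np.sort(edges, axis=1)
    uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
    mid = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])
    nodes10 = np.vstack([nodes, mid])
    mid_ids = len(nodes) + inverse.reshape(len(tets), 6)
    return nodes10, np.hstack([tets, mid_ids]).astype(np.int64)


def _boundary_faces(elements: np.ndarray):
    """Boundary faces of a TET10 mesh as (face6, owner_element) arrays."""
    faces = []
    owners = []
    for corners, mids in _TET_FACES:
        f = np.column_stack([elements[:, list(corners)], elements[:, list(mids)]])
        faces.append(f)
        owners.append(np.arange(len(elements)))
    faces = np.vstack(faces)
    owners = np.concatenate(owners)
    key = np.sort(faces[:, :3], axis=1)
    uniq, idx, counts = np.unique(key, axis=0, return_index=True,
                                  return_counts=True)
    sel = idx[counts == 1]
    return faces[sel], owners[sel]


def _face_geometry(nodes, faces6):
    """(areas, unit normals, centroids) of straight 6-node triangles."""
    p = nodes[faces6[:, :3]]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = 0.5 * np.linalg.norm(cr, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cr / (2 * areas)[:, None]
    return areas, normals, p.mean(axis=1)


def loft_mesh(geometry: TendonGeometry, max_edge_length: float,
              merge: bool = False) -> TendonMesh:
    """Mesh a parametric tendon geometry into labelled TET10 elements.

    Parameters
    ----------
    geometry : TendonGeometry
        Output of :func:`subtendon.geometry.make_archetype` (or compatible).
    max_edge_length : float
        Target edge length h (mm); no element edge exceeds 1.5 h.
    merge : bool
        If True, sub-tendons share their interface nodes (fully bonded
        conforming mesh, no interface pairs) - the merged-mesh oracle for
        the bonded interface model.
    """
    if max_edge_length <= 0:
        raise ValueError("max_edge_length must be positive")
    h = float(max_edge_length)
    params = geometry.partition_params
    if params is None:
        raise ValueError("geometry lacks analytic partition parameters")
    sec = _section_mesh_2d(params, h)
    n2d = len(sec.points)

    L = geometry.length
    n_layers = max(int(math.ceil(L / (0.7 * h))), 2)
    zs = np.linspace(0.0, L, n_layers + 1)
    angles = np.array([geometry.frame_rotation_at(z) for z in zs])

    # canonical (merged) ids: layer * n2d + point
    def canon(layer, pid):
        return layer * n2d + pid

    # per-sub-tendon local corner node numbering
    if merge:
        owner_sets = [np.ones(n2d, dtype=bool)]
    else:
        owner_sets = [sec.membership[:, si] for si in range(3)]

    meshes = []
    for si, used in enumerate(owner_sets):
        pids = np.flatnonzero(used)
        local = -np.ones(n2d, dtype=np.int64)
        local[pids] = np.arange(len(pids))
        # node coords: all layers of this sub-tendon's 2D points
        coords = np.empty((len(zs) * len(pids), 3))
        for li, z in enumerate(zs):
            rot = rotation_2d(angles[li])
            xy = sec.points[pids] @ rot.T
            coords[li * len(pids):(li + 1) * len(pids), :2] = xy
            coords[li * len(pids):(li + 1) * len(pids), 2] = z
        if merge:
            tris = sec.triangles
            labs = sec.tri_label
        else:
            sel = sec.tri_label == si
            tris = sec.triangles[sel]
            labs = sec.tri_label[sel]
        tets, tet_lab = [], []
        for li in range(n_layers):
            for tri, lab in zip(tris, labs):
                dec = [canon(li, tri[0]), canon(li, tri[1]), canon(li, tri[2]),
                       canon(li + 1, tri[0]), canon(li + 1, tri[1]),
                       canon(li + 1, tri[2])]
                outl = [li * len(pids) + local[tri[0]],
                        li * len(pids) + local[tri[1]],
                        li * len(pids) + local[tri[2]],
                        (li + 1) * len(pids) + local[tri[0]],
                        (li + 1) * len(pids) + local[tri[1]],
                        (li + 1) * len(pids) + local[tri[2]]]
                for t in _split_wedge(dec, outl):
                    tets.append(t)
                    tet_lab.append(lab)
        tets = np.asarray(tets, dtype=np.int64)
        tet_lab = np.asarray(tet_lab, dtype=np.int8)
        meshes.append((coords, tets, tet_lab))
        if merge:
            break

    # concatenate sub-meshes
    all_nodes, all_tets, all_labs, owner = [], [], [], []
    offset = 0
    for si, (coords, tets, labs) in enumerate(meshes):
        all_nodes.append(coords)
        all_tets.append(tets + offset)
        all_labs.append(labs)
        owner.append(np.full(len(coords), -1 if merge else si, dtype=np.int8))
        offset += len(coords)
    nodes = np.vstack(all_nodes)
    tets = np.vstack(all_tets)
    labels = np.concatenate(all_labs)
    owner = np.concatenate(owner)

    # fix orientation
    d = nodes[tets[:, 1:]] - nodes[tets[:, :1]]
    neg = np.linalg.det(d) < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2].copy(), tets[neg, 1].copy()

    nodes10, elements = _quadratic_from_linear(nodes, tets)
    owner = _extend_owner(owner, tets)

    twist_rate = math.radians(geometry.twist_deg) / L  # rad / mm
    mesh = TendonMesh(
        nodes=nodes10, elements=elements, elem_label=labels,
        face_sets={}, node_owner=owner, h=h,
        meta={"model_id": geometry.model_id, "length": L,
              "n_layers": n_layers, "merged": merge,
              "twist_rate": twist_rate},
    )
    _build_face_sets_and_pairs(mesh, L, merged=merge, twist_rate=twist_rate)
    mesh.validate()
    return mesh


def _extend_owner(owner, tets):
    # midside nodes inherit the owner of their edge (edges never cross
    # sub-tendons in the split mesh); ordering matches _quadratic_from_linear
    edges = np.sort(tets[:, _TET_EDGES].reshape(-1, 2), axis=1)
    uniq = np.unique(edges, axis=0)
    return np.concatenate([owner, owner[uniq[:, 0]]])


def _build_face_sets_and_pairs(mesh: TendonMesh, length: float,
                               merged: bool,
                               twist_rate: float = 0.0) -> None:
    nodes, elements = mesh.nodes, mesh.elements
    faces, owners = _boundary_faces(elements)
    face_label = mesh.elem_label[owners]
    zf = nodes[faces, 2]
    tol = 1e-6
    distal = np.all(zf < tol, axis=1)
    proximal = np.all(zf > length - tol, axis=1)

    # interface pairs by geometric coincidence between different owners
    if not merged:
        tree = cKDTree(nodes)
        cand = tree.query_pairs(PAIR_TOL, output_type="ndarray")
        if len(cand):
            diff = mesh.node_owner[cand[:, 0]] != mesh.node_owner[cand[:, 1]]
            cand = cand[diff]
        pair_a = cand[:, 0].astype(np.int64) if len(cand) else np.zeros(0, np.int64)
        pair_b = cand[:, 1].astype(np.int64) if len(cand) else np.zeros(0, np.int64)
    else:
        pair_a = pair_b = np.zeros(0, np.int64)

    has_partner = np.zeros(len(nodes), dtype=bool)
    partner_owner = [set() for _ in range(len(nodes))] if not merged else []
    for i, j in zip(pair_a, pair_b):
        has_partner[i] = has_partner[j] = True
        partner_owner[i].add(int(mesh.node_owner[j]))
        partner_owner[j].add(int(mesh.node_owner[i]))

    interface_face = has_partner[faces].all(axis=1) if not merged else \
        np.zeros(len(faces), dtype=bool)

    face_sets: dict[str, np.ndarray] = {}
    for si, s in enumerate(SUBTENDON_ORDER):
        face_sets[f"distal_{s.value}"] = faces[distal & (face_label == si)]
        face_sets[f"proximal_{s.value}"] = faces[proximal & (face_label == si)]
    exterior = ~(distal | proximal | interface_face)
    face_sets["exterior"] = faces[exterior]
    face_sets["interface"] = faces[interface_face]
    mesh.face_sets = face_sets

    if merged or not len(pair_a):
        return

    # tributary areas and averaged normals per (owner side, facing owner)
    areas, normals, _ = _face_geometry(nodes, faces)
    node_area = np.zeros((len(nodes), 3))   # facing owner -> lumped area
    node_normal = np.zeros((len(nodes), 3, 3))
    iface_ids = np.flatnonzero(interface_face)
    for fi in iface_ids:
        f = faces[fi]
        own = int(face_label[fi])
        # which owner is this face facing?  the common partner of its nodes
        common = set.intersection(*(partner_owner[n] for n in f)) - {own}
        if not common:
            continue
        other = min(common)
        c0, c1, c2, m01, m12, m02 = f
        subtris = ((c0, m01, m02), (c1, m12, m01), (c2, m02, m12),
                   (m01, m12, m02))
        for st in subtris:
            p = nodes[list(st)]
            cr = np.cross(p[1] - p[0], p[2] - p[0])
            a3 = 0.5 * np.linalg.norm(cr) / 3.0
            for n in st:
                node_area[n, other] += a3
                node_normal[n, other] += cr / 2.0 / 3.0
    # build pair records on the lower-owner side.  The longitudinal tangent
    # t1 follows the local (helical) fascicle direction ez + twist_rate *
    # (-y, x, 0): the lofted interface surface is generated by exactly these
    # helices, so frictionless sliding along t1 involves no motion in the
    # penalised n / t2 directions (a straight z tangent would geometrically
    # lock a twisted interface as the penalty stiffness grows).
    keep_a, keep_b = [], []
    frames, tribs = [], []
    for i, j in zip(pair_a, pair_b):
        oi, oj = int(mesh.node_owner[i]), int(mesh.node_owner[j])
        if oi > oj:
            i, j, oi, oj = j, i, oj, oi
        nvec = node_normal[i, oj]
        area = node_area[i, oj]
        if np.linalg.norm(nvec) < 1e-12:
            # junction-edge node without a fully-paired face: frame from
            # the in-plane direction towards the partner region
            nvec = node_normal[i].sum(axis=0)
            if np.linalg.norm(nvec) < 1e-12:
                nvec = np.array([1.0, 0.0, 0.0])
        n = nvec / np.linalg.norm(nvec)
        x, y = mesh.nodes[i, 0], mesh.nodes[i, 1]
        fibre = np.array([-twist_rate * y, twist_rate * x, 1.0])
        t1 = fibre - (fibre @ n) * n
        nt1 = np.linalg.norm(t1)
        if nt1 < 1e-8:  # degenerate (normal along the fibre); not expected
            t1 = np.array([1.0, 0.0, 0.0]) - n[0] * n
            nt1 = np.linalg.norm(t1)
        t1 = t1 / nt1
        t2 = np.cross(n, t1)
        keep_a.append(i)
        keep_b.append(j)
        frames.append(np.stack([n, t1, t2]))
        tribs.append(area)
    mesh.pair_a = np.asarray(keep_a, dtype=np.int64)
    mesh.pair_b = np.asarray(keep_b, dtype=np.int64)
    mesh.pair_frames = np.asarray(frames)
    mesh.pair_area = np.asarray(tribs)


def merge_interfaces(mesh: TendonMesh) -> TendonMesh:
    """Collapse all interface pairs into shared nodes (bonded oracle mesh)."""
    n = mesh.n_nodes
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(mesh.pair_a, mesh.pair_b):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    root = np.array([find(i) for i in range(n)])
    used = np.unique(root)
    remap = -np.ones(n, dtype=np.int64)
    remap[used] = np.arange(len(used))
    newmap = remap[root]

    elements = newmap[mesh.elements]
    face_sets = {k: newmap[v] if len(v) else v.copy()
                 for k, v in mesh.face_sets.items()}
    merged = TendonMesh(
        nodes=mesh.nodes[used], elements=elements,
        elem_label=mesh.elem_label.copy(), face_sets=face_sets,
        node_owner=np.full(len(used), -1, dtype=np.int8), h=mesh.h,
        meta={**mesh.meta, "merged": True},
    )
    merged.validate()
    return merged


# ---------------------------------------------------------------------------
# structured single-material bar (verification oracle mesh)
# ---------------------------------------------------------------------------

def box_bar_mesh(lx: float, ly: float, lz: float, h: float,
                 label: SubTendonID = SubTendonID.SOL) -> TendonMesh:
    """Structured TET10 mesh of an lx x ly x lz bar (single sub-tendon).

    Used by the verification suite (exact cross-section area and volume,
    closed-form bar solution).  Distal face at z = 0, proximal at z = lz.
    """
    nx = max(int(round(lx / h)), 1)
    ny = max(int(round(ly / h)), 1)
    nz = max(int(round(lz / h)), 1)
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn triangulation of each cube: 6 tets around the main diagonal
    corner_perms = [
        (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
        (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
    ]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = [nid(i + a, j + b, k + d)
                     for a in (0, 1) for b in (0, 1) for d in (0, 1)]
                # c index bits: (x, y, z) -> 4a + 2b + d
                for p in corner_perms:
                    tets.append([c[p[0]], c[p[1]], c[p[2]], c[p[3]]])
    tets = np.asarray(tets, dtype=np.int64)
    d = nodes[tets[:, 1:]] - nodes[tets[:, :1]]
    neg = np.linalg.det(d) < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2].copy(), tets[neg, 1].copy()

    nodes10, elements = _quadratic_from_linear(nodes, tets)
    si = SUBTENDON_ORDER.index(label)
    mesh = TendonMesh(
        nodes=nodes10, elements=elements,
        elem_label=np.full(len(elements), si, dtype=np.int8),
        face_sets={}, node_owner=np.full(len(nodes10), si, dtype=np.int8),
        h=h, meta={"bar": (lx, ly, lz), "merged": True},
    )
    _build_face_sets_and_pairs(mesh, lz, merged=True)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# mesh convergence
# ---------------------------------------------------------------------------

def converge_mesh(geometry: TendonGeometry, materials, load, interface=None,
                  criterion: float = 0.01, refinement_factor: float = 1.4,
                  h0: float | None = None, max_refinements: int = 5,
                  solver_options=None):
    """Refine the mesh until the monitored outcome changes by < ``criterion``.

    The monitored scalar is the mean longitudinal displacement of the
    proximal soleus face (the outcome the displacement analysis reports).
    Returns ``(chosen max_edge_length, convergence table)`` where the chosen
    edge length is the coarser member of the converged pair.
    """
    from .fe import solve_static, InterfaceModel
    from .postprocess import mean_face_displacement

    if criterion <= 0:
        raise ValueError("criterion must be positive")
    if interface is None:
        interface = InterfaceModel(mode="bonded")
    if h0 is None:
        h0 = geometry.length / 8.0

    rows = []
    prev = None
    h = float(h0)
    for level in range(max_refinements + 1):
        mesh = loft_mesh(geometry, h)
        sol = solve_static(mesh, materials, load, interface,
                           options=solver_options)
        face = mesh.face_sets["proximal_SOL"]
        disp = mean_face_displacement(sol, face)
        change = float("nan") if prev is None else abs(disp - prev[1]) / abs(prev[1])
        rows.append({"level": level, "max_edge_length": h,
                     "n_elements": mesh.n_elements,
                     "monitored_mm": disp, "rel_change": change})
        if prev is not None and change < criterion:
            return prev[0], pd.DataFrame(rows)
        prev = (h, disp)
        h = h / refinement_factor
    raise RuntimeError(
        f"mesh not converged to {criterion:.2%} within "
        f"{max_refinements} refinements")
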