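"""Static, geometrically nonlinear FE solution of the loaded sub-tendon mesh.

Total-Lagrangian formulation on TET10 elements (4-point quadrature, straight
edges hence affine geometry), compressible neo-Hookean material, Newton
iteration per load-ramp step with a sparse direct solve.

The sub-tendon interfaces are matched node-pair penalties on the conforming
interface meshes.  The normal (n) and in-plane transverse (t2) relative
displacements are penalised bilaterally - the discrete analogue of a
translational joint that resists separation and interpenetration alike while
leaving the longitudinal direction to the interface law:

* ``frictionless``: no longitudinal force;
* ``bonded``: longitudinal tie with penalty k_t;
* ``frictional``: elastic-predictor / return-mapping Coulomb law with the
  tangential trial force capped at mu times the bilateral normal force.

Loads are applied as uniform tractions over the proximal face of each loaded
sub-tendon (consistent nodal loads), pulling in +z; distal faces are fully
fixed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .core import SUBTENDON_ORDER, SubTendonID
from .material import MaterialMap, pk1_stress, pk1_tangent, cauchy_from_pk1
from .meshing import TendonMesh

__all__ = [
    "LoadCase",
    "InterfaceModel",
    "SolverOptions",
    "SolutionField",
    "SolverError",
    "solve_static",
    "interface_force_update",
    "run_load_cases",
    "paper_interface_grid",
    "isolated_load_grid",
    "external_load_vector",
    "PAPER_MU_GRID",
]

#: Friction coefficients of the interface sweep.
PAPER_MU_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)

# 4-point Gauss rule for tetrahedra (degree 2)
_QA = 0.5854101966249685
_QB = 0.1381966011250105
_QPOINTS = np.array([
    [_QA, _QB, _QB],
    [_QB, _QA, _QB],
    [_QB, _QB, _QA],
    [_QB, _QB, _QB],
])
_QWEIGHTS = np.full(4, 0.25)


class SolverError(RuntimeError):
    """Newton divergence or a singular system; carries the residual log."""

    def __init__(self, message: str, log=None):
        super().__init__(message)
        self.log = log or []


@dataclass(frozen=True)
class LoadCase:
    """Proximal tensile loads on a set of sub-tendons; distal faces fixed."""

    loaded: frozenset
    force_per_subtendon: float = 100.0  # N
    ramp_steps: int = 10
    #: "fixed" clamps every distal dof (the calcaneal insertion); "roller"
    #: fixes only the longitudinal dof plus minimal lateral anchors, giving
    #: homogeneous deformation for the uniaxial verification problems.
    distal_constraint: str = "fixed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "loaded", frozenset(self.loaded))
        if self.force_per_subtendon < 0:
            raise ValueError("force must be non-negative")
        if self.ramp_steps < 1:
            raise ValueError("ramp_steps must be >= 1")
        if self.distal_constraint not in ("fixed", "roller"):
            raise ValueError("distal_constraint must be 'fixed' or 'roller'")

    @property
    def label(self) -> str:
        return "+".join(sorted(s.value for s in self.loaded))


@dataclass(frozen=True)
class InterfaceModel:
    """Sub-tendon interface behaviour: frictionless, frictional or bonded.

    Penalty stiffnesses are per unit tributary area (MPa/mm).
    """

    mode: str
    mu: float = 0.0
    k_n: float = 1e3
    k_t: float = 1e3

    def __post_init__(self) -> None:
        if self.mode not in ("frictionless", "frictional", "bonded"):
            raise ValueError(f"unknown interface mode {self.mode!r}")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.k_n <= 0 or self.k_t <= 0:
            raise ValueError("penalty stiffnesses must be positive")

    @property
    def label(self) -> str:
        if self.mode == "frictional":
            return f"frictional_mu{self.mu:g}"
        return self.mode


@dataclass
class SolverOptions:
    tol: float = 1e-6          # relative residual
    abs_tol: float = 1e-9      # N; fallback for zero-load steps
    max_iterations: int = 50
    line_search_cuts: int = 12  # backtracking halvings per Newton step
    #: normal-gap smoothing length (mm) of the regularised Coulomb law
    friction_smoothing: float = 1e-6


@dataclass
class SolutionField:
    """Converged solution: displacements, centroid stresses, interface state."""

    mesh: TendonMesh
    u: np.ndarray                       # (N, 3) nodal displacements, mm
    cauchy: np.ndarray                  # (E, 3, 3) centroid Cauchy stress, MPa
    interface_normal_force: np.ndarray  # (P,) N (signed; + separation)
    interface_tangential_force: np.ndarray  # (P, 2) N, (t1, t2) components
    interface_slip: np.ndarray          # (P,) bool
    reactions: np.ndarray               # (N, 3) N at fixed nodes, zero elsewhere
    external: np.ndarray                # (N, 3) applied nodal loads, N
    log: list = field(default_factory=list)
    converged: bool = True

    def equilibrium_residual(self) -> np.ndarray:
        """| sum reactions + sum applied | / |applied| per axis."""
        applied = self.external.sum(axis=0)
        resid = self.reactions.sum(axis=0) + applied
        scale = max(np.linalg.norm(applied), 1e-12)
        return np.abs(resid) / scale


# ---------------------------------------------------------------------------
# interface constitutive update (pure function)
# ---------------------------------------------------------------------------

#: tanh argument beyond which a regularised pair counts as slipping
#: (tanh(2.6467) = 0.99, i.e. the force has reached 99% of the Coulomb cap).
_SLIP_TANH = 2.6466524123622457


def interface_force_update(d_local: np.ndarray, area, interface: InterfaceModel,
                           slip_state=None, smoothing: float = 0.0):
    """Penalty interface forces from relative displacement in the local frame.

    Parameters
    ----------
    d_local : (..., 3) array
        Relative displacement (node_a - node_b) in frame components
        (n, t1, t2): interface normal, longitudinal tangent, in-plane
        transverse tangent.
    area : array
        Tributary area per pair (mm^2).
    interface : InterfaceModel
    slip_state : array, optional
        Accumulated plastic slip along t1 (frictional mode only).
    smoothing : float
        0 gives the sharp elastic-predictor / return-mapping Coulomb law
        (trial force capped at mu |N|).  A positive value (mm) gives the
        regularised law the solver iterates on: the cap uses the smooth
        normal-gap magnitude sqrt(dn^2 + smoothing^2) and the clip is
        replaced by a tanh, which is what makes Newton convergent; a pair is
        flagged ``slip`` once the force reaches 99% of the cap.

    Returns
    -------
    (f_n, f_t1, f_t2, slip_flag) : forces (N) that the penalty applies to
        node_a (restoring, i.e. f = -k * gap * area), and the stick/slip
        flag.
    """
    d = np.asarray(d_local, dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValueError("non-finite relative displacement")
    area = np.asarray(area, dtype=float)
    dn, dt1, dt2 = d[..., 0], d[..., 1], d[..., 2]
    f_n = -interface.k_n * area * dn
    f_t2 = -interface.k_t * area * dt2
    if interface.mode == "frictionless":
        f_t1 = np.zeros_like(f_n)
        slip = np.zeros_like(f_n, dtype=bool)
    elif interface.mode == "bonded":
        f_t1 = -interface.k_t * area * dt1
        slip = np.zeros_like(f_n, dtype=bool)
    else:
        sp = np.zeros_like(dt1) if slip_state is None else np.asarray(slip_state)
        trial = -interface.k_t * area * (dt1 - sp)
        if smoothing > 0:
            cap = interface.mu * interface.k_n * area * np.sqrt(
                dn * dn + smoothing * smoothing)
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.where(cap > 0, trial / np.maximum(cap, 1e-300), 0.0)
            f_t1 = cap * np.tanh(x)
            slip = np.abs(x) > _SLIP_TANH
        else:
            cap = interface.mu * np.abs(f_n)
            slip = np.abs(trial) > cap
            f_t1 = np.clip(trial, -cap, cap)
    return f_n, f_t1, f_t2, slip


# ---------------------------------------------------------------------------
# element precomputation
# ---------------------------------------------------------------------------

def _tet10_shape_gradients():
    """dN/d(xi) for the 10 shape functions at given natural points."""
    def grads(xi, eta, zeta):
        l1, l2, l3 = xi, eta, zeta
        l0 = 1.0 - xi - eta - zeta
        dl = np.array([[-1.0, -1.0, -1.0],
                       [1.0, 0.0, 0.0],
                       [0.0, 1.0, 0.0],
                       [0.0, 0.0, 1.0]])
        lam = np.array([l0, l1, l2, l3])
        g = np.zeros((10, 3))
        for c in range(4):
            g[c] = (4.0 * lam[c] - 1.0) * dl[c]
        edges = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
        for m, (a, b) in enumerate(edges):
            g[4 + m] = 4.0 * (lam[a] * dl[b] + lam[b] * dl[a])
        return g

    qp = np.array([grads(*p) for p in _QPOINTS])       # (4, 10, 3)
    centroid = grads(0.25, 0.25, 0.25)                  # (10, 3)
    return qp, centroid


_DN_QP, _DN_CENTROID = _tet10_shape_gradients()


class _ElementData:
    """Per-element quadrature data and assembly index arrays."""

    def __init__(self, mesh: TendonMesh, materials: MaterialMap):
        X = mesh.nodes[mesh.elements[:, :4]]
        J = np.swapaxes(X[:, 1:] - X[:, :1], 1, 2)      # (E, 3, 3) columns
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise SolverError("non-positive Jacobian in mesh")
        Jinv = np.linalg.inv(J)
        # dN/dX at qps: (E, Q, 10, 3)
        self.dNdX = np.einsum("qam,emk->eqak", _DN_QP, Jinv)
        self.dNdX_c = np.einsum("am,emk->eak", _DN_CENTROID, Jinv)
        self.wq = detJ[:, None] / 6.0 * _QWEIGHTS[None, :]  # (E, Q)
        self.vol = detJ / 6.0

        lab = mesh.elem_label
        c10 = np.empty(len(lab))
        d1 = np.empty(len(lab))
        for si, s in enumerate(SUBTENDON_ORDER):
            if np.any(lab == si):
                if s not in materials:
                    raise ValueError(f"material map missing {s}")
                c10[lab == si] = materials[s].C10
                d1[lab == si] = materials[s].D1
        self.c10, self.d1 = c10, d1

        dof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(len(lab), 30)
        self.edof = dof
        self.rows = np.repeat(dof, 30, axis=1).ravel()
        self.cols = np.tile(dof, (1, 30)).ravel()


def _deformation_gradients(ed: _ElementData, u_e: np.ndarray):
    F = np.einsum("eai,eqaJ->eqiJ", u_e, ed.dNdX)
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    F[..., 2, 2] += 1.0
    return F


def _internal_force(ed: _ElementData, F):
    P = pk1_stress(F, ed.c10[:, None], ed.d1[:, None])
    return np.einsum("eq,eqiJ,eqaJ->eai", ed.wq, P, ed.dNdX), P


def _stiffness_values(ed: _ElementData, F):
    A = pk1_tangent(F, ed.c10[:, None], ed.d1[:, None])
    tmp = np.einsum("eqaJ,eqiJkL->eqaikL", ed.dNdX, A, optimize=True)
    K = np.einsum("eq,eqaikL,eqbL->eaibk", ed.wq, tmp, ed.dNdX, optimize=True)
    return K.reshape(len(ed.c10), 900).ravel()


# ---------------------------------------------------------------------------
# boundary conditions and loads
# ---------------------------------------------------------------------------

def _fixed_nodes(mesh: TendonMesh) -> np.ndarray:
    ids = []
    for s in SUBTENDON_ORDER:
        faces = mesh.face_sets.get(f"distal_{s.value}")
        if faces is not None and len(faces):
            ids.append(faces.ravel())
    if not ids:
        raise ValueError("mesh has no distal face sets to fix")
    return np.unique(np.concatenate(ids))


def external_load_vector(mesh: TendonMesh, load: LoadCase) -> np.ndarray:
    """Consistent nodal loads of a uniform +z traction on the proximal faces.

    For a straight-edged 6-node triangle under uniform traction the
    consistent load puts one third of the face force on each midside node and
    nothing on the corners.
    """
    f = np.zeros((mesh.n_nodes, 3))
    for s in load.loaded:
        faces = mesh.face_sets.get(f"proximal_{SubTendonID(s).value}")
        if faces is None or not len(faces):
            raise ValueError(f"no proximal face set for loaded sub-tendon {s}")
        p = mesh.nodes[faces[:, :3]]
        areas = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
        total = areas.sum()
        traction = load.force_per_subtendon / total
        for m in range(3, 6):
            np.add.at(f[:, 2], faces[:, m], traction * areas / 3.0)
    return f


# ---------------------------------------------------------------------------
# main solver
# ---------------------------------------------------------------------------

def solve_static(mesh: TendonMesh, materials: MaterialMap, load: LoadCase,
                 interface: InterfaceModel, options: SolverOptions | None = None,
                 u0: np.ndarray | None = None) -> SolutionField:
    """Solve the ramped static problem by Newton iteration.

    Per ramp step the external load is the step fraction of the total; the
    Newton iteration runs on the total-Lagrangian residual (internal forces
    + interface penalty forces - external tractions) until the relative
    residual drops below ``options.tol``.  ``u0`` warm-starts the first step
    (useful when sweeping the friction coefficient).
    """
    options = options or SolverOptions()
    ed = _ElementData(mesh, materials)
    n = mesh.n_nodes
    ndof = 3 * n

    fixed = _fixed_nodes(mesh)
    if load.distal_constraint == "fixed":
        fixed_dofs = (3 * fixed[:, None] + np.arange(3)).ravel()
    else:  # roller: z on the whole face, lateral anchors on two nodes
        xy = mesh.nodes[fixed, :2]
        anchor = fixed[np.argmin(np.linalg.norm(xy - xy.mean(axis=0), axis=1))]
        far = fixed[np.argmax(np.abs(mesh.nodes[fixed, 0]
                                     - mesh.nodes[anchor, 0]))]
        fixed_dofs = np.unique(np.concatenate([
            3 * fixed + 2, [3 * anchor, 3 * anchor + 1, 3 * far + 1]]))
    free_mask = np.ones(ndof, dtype=bool)
    free_mask[fixed_dofs] = False
    free = np.flatnonzero(free_mask)
    ridx = -np.ones(ndof, dtype=np.int64)
    ridx[free] = np.arange(len(free))

    f_ext_total = external_load_vector(mesh, load).ravel()

    # sparse pattern: element blocks + interface pair blocks
    P = len(mesh.pair_a)
    if P:
        pa = (3 * mesh.pair_a[:, None] + np.arange(3))
        pb = (3 * mesh.pair_b[:, None] + np.arange(3))
        pdof = np.hstack([pa, pb])                     # (P, 6)
        prows = np.repeat(pdof, 6, axis=1).ravel()
        pcols = np.tile(pdof, (1, 6)).ravel()
        rows = np.concatenate([ed.rows, prows])
        cols = np.concatenate([ed.cols, pcols])
    else:
        rows, cols = ed.rows, ed.cols
    keep = free_mask[rows] & free_mask[cols]
    krows, kcols = ridx[rows[keep]], ridx[cols[keep]]

    u = np.zeros((n, 3)) if u0 is None else np.array(u0, dtype=float, copy=True)
    slip_state = np.zeros(P)
    frames = mesh.pair_frames
    areas = mesh.pair_area
    log: list[dict] = []

    eps = options.friction_smoothing

    def local_gaps(u_arr):
        ua = u_arr.reshape(n, 3)[mesh.pair_a]
        ub = u_arr.reshape(n, 3)[mesh.pair_b]
        return np.einsum("pij,pj->pi", frames, ua - ub)  # (P,) in (n, t1, t2)

    def interface_terms(u_flat):
        """Forces (global) and 6x6 stiffness blocks of the interface law.

        The frictional branch is the smooth regularised Coulomb law of
        :func:`interface_force_update` with ``smoothing > 0``, which keeps
        the residual differentiable and the Newton loop convergent.
        """
        if not P:
            return np.zeros(ndof), np.zeros(0)
        d = local_gaps(u_flat)
        dn, dt1, dt2 = d[:, 0], d[:, 1], d[:, 2]
        kt = np.zeros((P, 3, 3))
        kt[:, 0, 0] = interface.k_n * areas
        kt[:, 2, 2] = interface.k_t * areas
        f_n, f_t1, f_t2, _ = interface_force_update(
            d, areas, interface, slip_state, smoothing=eps)
        if interface.mode == "bonded":
            kt[:, 1, 1] = interface.k_t * areas
        elif interface.mode == "frictional":
            c = interface.k_t * areas
            m = interface.mu * interface.k_n * areas
            g = np.sqrt(dn * dn + eps * eps)
            cap = m * g
            trial = -c * (dt1 - slip_state)
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.where(cap > 0, trial / np.maximum(cap, 1e-300), 0.0)
            sech2 = 1.0 / np.cosh(np.clip(x, -40, 40)) ** 2
            dcap_dn = m * dn / g
            # residual contribution is -f_t1
            kt[:, 1, 1] = c * sech2
            kt[:, 1, 0] = -dcap_dn * (np.tanh(x) - x * sech2)
        f_local = np.stack([f_n, f_t1, f_t2], axis=-1)
        f_glob = np.einsum("pij,pi->pj", frames, f_local)  # forces on node a
        fvec = np.zeros((n, 3))
        np.add.at(fvec, mesh.pair_a, -f_glob)  # residual convention: +f_int
        np.add.at(fvec, mesh.pair_b, f_glob)
        # rotate the local tangent to global axes: A^T kt A with A rows the
        # frame vectors
        kg = np.einsum("pmi,pmn,pnj->pij", frames, kt, frames)
        kblock = np.empty((P, 6, 6))
        kblock[:, :3, :3] = kg
        kblock[:, 3:, 3:] = kg
        kblock[:, :3, 3:] = -kg
        kblock[:, 3:, :3] = -kg
        return fvec.ravel(), kblock.reshape(P, 36).ravel()

    def residual(u_flat, lam):
        u_e = u_flat.reshape(n, 3)[mesh.elements]
        F = _deformation_gradients(ed, u_e)
        if np.linalg.det(F).min() <= 0:
            return None, F, None  # inverted element; caller must backtrack
        fint_e, _ = _internal_force(ed, F)
        r = np.zeros(ndof)
        np.add.at(r, ed.edof.ravel(), fint_e.reshape(-1, 30).ravel())
        f_if, kvals_if = interface_terms(u_flat)
        r += f_if
        return r - lam * f_ext_total, F, kvals_if

    def newton(lam, tol, step, log_entry):
        nonlocal u
        history = log_entry["residuals"]
        r, F, kvals_if = residual(u.ravel(), lam)
        if r is None:
            raise SolverError(f"inverted element entering step {step}", log=log)
        rnorm = np.linalg.norm(r[free])
        for it in range(options.max_iterations + 1):
            history.append(rnorm)
            if rnorm <= tol:
                return
            kvals = _stiffness_values(ed, F)
            vals = np.concatenate([kvals, kvals_if]) if P else kvals
            K = coo_matrix((vals[keep], (krows, kcols)),
                           shape=(len(free), len(free))).tocsc()
            try:
                # the matrix is structurally symmetric and strongly diagonal;
                # SymmetricMode with a relaxed pivot threshold factorises
                # several times faster than the unsymmetric default
                du = splu(K, permc_spec="MMD_AT_PLUS_A",
                          options={"SymmetricMode": True,
                                   "DiagPivotThresh": 0.001}).solve(-r[free])
            except RuntimeError as exc:  # singular factorisation
                raise SolverError(f"singular system at step {step}: {exc}",
                                  log=log) from exc
            # backtracking line search on the residual norm (also guards
            # against element inversion under large rotation increments)
            alpha = 1.0
            for _ in range(options.line_search_cuts + 1):
                u_try = u.ravel().copy()
                u_try[free] += alpha * du
                r_try, F_try, k_try = residual(u_try, lam)
                if r_try is not None:
                    rn_try = np.linalg.norm(r_try[free])
                    if rn_try < rnorm or rn_try <= tol:
                        u = u_try.reshape(n, 3)
                        r, F, kvals_if, rnorm = r_try, F_try, k_try, rn_try
                        break
                alpha *= 0.5
            else:
                raise SolverError(
                    f"line search failed at ramp step {step}, iteration {it} "
                    f"(residual {rnorm:.3e})", log=log)
        raise SolverError(
            f"Newton did not converge at ramp step {step} "
            f"(residual {history[-1]:.3e}, tol {tol:.3e})", log=log)

    ref_force = np.linalg.norm(f_ext_total[free])
    total_steps = load.ramp_steps
    frictional = P > 0 and interface.mode == "frictional"
    iface_state = None
    for step in range(1, total_steps + 1):
        lam = step / total_steps
        tol = max(options.tol * lam * ref_force, options.abs_tol)
        entry = {"step": step, "lambda": lam, "residuals": []}
        log.append(entry)
        newton(lam, tol, step, entry)
        entry["iterations"] = len(entry["residuals"]) - 1
        if P:
            # record the interface state before the slip commit (afterwards
            # the shifted stick reference would mask the slip flags)
            d = local_gaps(u.ravel())
            iface_state = interface_force_update(
                d, areas, interface, slip_state, smoothing=eps)
        # commit frictional slip state at the converged step
        if frictional:
            f_n, f_t1, _, slip = iface_state
            with np.errstate(divide="ignore", invalid="ignore"):
                upd = d[:, 1] + np.where(areas > 0,
                                         f_t1 / (interface.k_t * areas), 0.0)
            slip_state = np.where(slip, upd, slip_state)

    # recover fields at the final state
    u_e = u[mesh.elements]
    Fc = np.einsum("eai,eaJ->eiJ", u_e, ed.dNdX_c)
    Fc[..., 0, 0] += 1.0
    Fc[..., 1, 1] += 1.0
    Fc[..., 2, 2] += 1.0
    Pc = pk1_stress(Fc, ed.c10, ed.d1)
    cauchy = cauchy_from_pk1(Fc, Pc)

    if P:
        f_n, f_t1, f_t2, slip = iface_state
        tang = np.stack([f_t1, f_t2], axis=-1)
    else:
        f_n = np.zeros(0)
        tang = np.zeros((0, 2))
        slip = np.zeros(0, dtype=bool)

    # support forces at the fixed dofs: (internal + interface) there
    r_final, _, _ = residual(u.ravel(), 1.0)
    reactions = np.zeros((n, 3))
    reactions.ravel()[fixed_dofs] = (r_final[fixed_dofs]
                                     + f_ext_total[fixed_dofs])

    return SolutionField(
        mesh=mesh, u=u, cauchy=cauchy,
        interface_normal_force=f_n, interface_tangential_force=tang,
        interface_slip=slip,
        reactions=reactions,
        external=f_ext_total.reshape(n, 3),
        log=log, converged=True,
    )


def run_load_cases(mesh: TendonMesh, materials: MaterialMap,
                   interfaces, loads, options: SolverOptions | None = None,
                   warm_start: bool = True):
    """Solve the cross-product of interface models and load cases.

    Results come back as a dict keyed by ``(interface.label, load.label)`` in
    deterministic order.  Within one load case, solutions warm-start the
    next interface model in the given order (sweeps should order frictional
    models by increasing mu); warm-started solves apply the full load in a
    single step, which is consistent with the monotone-ramp treatment of
    friction (the stick reference starts from the unloaded state either
    way) and saves re-ramping from an already-deformed estimate.
    """
    from dataclasses import replace

    interfaces = list(interfaces)
    loads = list(loads)
    if not interfaces or not loads:
        raise ValueError("interface and load grids must be non-empty")
    out: dict[tuple[str, str], SolutionField] = {}
    for ld in loads:
        u_prev = None
        for iface in interfaces:
            warm = warm_start and u_prev is not None
            case = replace(ld, ramp_steps=1) if warm else ld
            try:
                sol = solve_static(mesh, materials, case, iface,
                                   options=options,
                                   u0=u_prev if warm else None)
            except SolverError as exc:
                raise SolverError(
                    f"[interface={iface.label}, load={ld.label}] {exc}",
                    log=exc.log) from exc
            out[(iface.label, ld.label)] = sol
            u_prev = sol.u
    return out


def paper_interface_grid(k_n: float = 1e3, k_t: float = 1e3):
    """The sweep's seven interface models: frictionless, mu grid, bonded."""
    grid = [InterfaceModel("frictionless", k_n=k_n, k_t=k_t)]
    grid += [InterfaceModel("frictional", mu=m, k_n=k_n, k_t=k_t)
             for m in PAPER_MU_GRID]
    grid.append(InterfaceModel("bonded", k_n=k_n, k_t=k_t))
    return grid


def isolated_load_grid(force: float = 100.0, ramp_steps: int = 10):
    """LG-only, MG-only, SOL-only load cases."""
    return [LoadCase(loaded=frozenset({s}), force_per_subtendon=force,
                     ramp_steps=ramp_steps) for s in SUBTENDON_ORDER]
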