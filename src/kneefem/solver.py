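"""Quasi-static small-strain finite-element solver.

Element technology: 4-node linear tetrahedra (isotropic elasticity),
triangular membrane shells (in-plane stiffness × thickness, no bending),
and 2-node tension-only trusses with piecewise-linear strain–tension laws.
Contact is node-to-surface penalty with penalty-regularised Coulomb friction
(compression-only for ordinary pairs, bonded for tied pairs).

The two nonlinearities — the contact active set and the truss tension/slack
set — are resolved by an outer fixed-point loop around a sparse linear solve:
each iteration freezes contact projections and truss law segments at the
current displacement, solves the linearised problem, and repeats until both
active sets are stable and the displacement increment is below tolerance.
Floating parts whose support arrives only through contact are held by weak
stabilisation springs during the iterations; a final stabilisation-free solve
with the converged active sets restores exact global equilibrium.

Units: mm, N, MPa (N/mm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from kneefem.mesh import Mesh
from kneefem.materials import MaterialField
from kneefem.model import KneeModel, BoundaryConditions, build_external_forces


class SolverError(RuntimeError):
    pass


class NonConvergenceError(SolverError):
    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


# ------------------------------------------------------------- elements

def isotropic_D(E: float, nu: float) -> np.ndarray:
    """6×6 isotropic elasticity matrix (engineering shear strains)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def tet4_stiffness(nodes: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12×12 stiffness of a linear tetrahedron.

    Symmetric positive-semidefinite with exactly six zero-energy rigid-body
    modes. Raises on a degenerate (non-positive-volume) element.
    """
    nodes = np.asarray(nodes, dtype=float).reshape(4, 3)
    B, V = _tet_B(nodes)
    if V <= 0:
        raise SolverError("degenerate tetrahedron (non-positive volume)")
    D = isotropic_D(E, nu)
    return V * B.T @ D @ B


def _tet_B(nodes: np.ndarray) -> tuple[np.ndarray, float]:
    J = nodes[1:] - nodes[0]
    detJ = np.linalg.det(J)
    V = detJ / 6.0
    if V <= 1e-14:
        raise SolverError("degenerate tetrahedron (non-positive volume)")
    grads = np.zeros((4, 3))
    grads[1:] = np.linalg.inv(J).T
    grads[0] = -grads[1:].sum(axis=0)
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B, V


def shell_membrane_stiffness(
    triangle: np.ndarray, thickness: float = 1.0, E: float = 1000.0, nu: float = 0.4
) -> np.ndarray:
    """9×9 membrane stiffness of a triangular shell (no bending).

    Constant-strain triangle in the element plane under plane stress, scaled
    by thickness; out-of-plane displacement carries no stiffness.
    """
    p = np.asarray(triangle, dtype=float).reshape(3, 3)
    e1 = p[1] - p[0]
    nvec = np.cross(e1, p[2] - p[0])
    A2 = np.linalg.norm(nvec)
    if A2 <= 1e-14:
        raise SolverError("zero-area shell triangle")
    nvec = nvec / A2
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(nvec, e1)
    A = A2 / 2.0
    # local 2-D coordinates
    xy = np.column_stack([(p - p[0]) @ e1, (p - p[0]) @ e2])
    x, y = xy[:, 0], xy[:, 1]
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
    B = np.zeros((3, 6))
    B[0, 0::2] = b
    B[1, 1::2] = c
    B[2, 0::2] = c
    B[2, 1::2] = b
    B /= 2 * A
    Dps = E / (1 - nu**2) * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])
    Kloc = thickness * A * B.T @ Dps @ B  # 6×6
    # map local (u1,u2) per node to global (x,y,z)
    T = np.zeros((6, 9))
    for a in range(3):
        T[2 * a, 3 * a : 3 * a + 3] = e1
        T[2 * a + 1, 3 * a : 3 * a + 3] = e2
    return T.T @ Kloc @ T


# ------------------------------------------------------------- assembly

def _assemble_tets(mesh: Mesh, materials: MaterialField) -> sp.csr_matrix:
    tets = mesh.tets
    m = len(tets)
    if m == 0:
        n = 3 * mesh.n_nodes
        return sp.csr_matrix((n, n))
    p = mesh.points[tets]  # (m,4,3)
    J = p[:, 1:] - p[:, :1]
    V = np.linalg.det(J) / 6.0
    if np.any(V <= 0):
        raise SolverError(f"degenerate tetrahedra at {np.where(V <= 0)[0][:10].tolist()}")
    invJT = np.linalg.inv(J).transpose(0, 2, 1)
    grads = np.zeros((m, 4, 3))
    grads[:, 1:] = invJT
    grads[:, 0] = -invJT.sum(axis=1)
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    E, nu = materials.E, materials.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((m, 6, 6))
    D[:, :3, :3] = lam[:, None, None]
    D[:, np.arange(3), np.arange(3)] += 2 * mu[:, None]
    D[:, np.arange(3, 6), np.arange(3, 6)] = mu[:, None]
    Ke = np.einsum("m,mia,mij,mjb->mab", V, B, D, B, optimize=True)
    dofs = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def _assemble_shells(mesh: Mesh, shell_props: dict) -> sp.csr_matrix:
    n = 3 * mesh.n_nodes
    if len(mesh.tris) == 0:
        return sp.csr_matrix((n, n))
    rows, cols, vals = [], [], []
    for tri in mesh.tris:
        Ke = shell_membrane_stiffness(
            mesh.points[tri],
            thickness=shell_props.get("thickness", 1.0),
            E=shell_props.get("E", 1000.0),
            nu=shell_props.get("nu", 0.4),
        )
        dofs = (3 * tri[:, None] + np.arange(3)).ravel()
        rows.append(np.repeat(dofs, 9))
        cols.append(np.tile(dofs, 9))
        vals.append(Ke.ravel())
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()


# ------------------------------------------------------------- trusses

@dataclass
class _TrussState:
    active: np.ndarray  # bool per truss
    segment: np.ndarray  # int id of law segment per truss (for set comparison)
    strain: np.ndarray
    tension: np.ndarray


def _truss_system(mesh: Mesh, laws: dict, u: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray, _TrussState]:
    """Linearised truss contribution at displacement u: (K_t, f_t, state).

    Each active truss contributes k_seg/L0 · (n n^T) stiffness blocks plus a
    constant-force correction so that tension T(ε) = c + k_seg·ε is represented
    exactly on the current law segment.
    """
    n = 3 * mesh.n_nodes
    t = len(mesh.trusses)
    K = sp.csr_matrix((n, n))
    f = np.zeros(n)
    if t == 0:
        return K, f, _TrussState(np.zeros(0, bool), np.zeros(0, int), np.zeros(0), np.zeros(0))
    rows, cols, vals = [], [], []
    strain = np.zeros(t)
    tension = np.zeros(t)
    active = np.zeros(t, dtype=bool)
    segment = np.full(t, -1, dtype=int)
    uu = u.reshape(-1, 3)
    for e, (n0, n1) in enumerate(mesh.trusses):
        law = laws[mesh.truss_names[e]]
        X0, X1 = mesh.points[n0], mesh.points[n1]
        axis = X1 - X0
        L0 = np.linalg.norm(axis)
        axis = axis / L0
        eps = float(axis @ (uu[n1] - uu[n0])) / L0
        strain[e] = eps
        T = law.tension(eps)
        tension[e] = T
        if eps <= 0:
            continue
        active[e] = True
        k_seg = law.slope(eps)
        bps = [p[0] for p in law.breakpoints]
        segment[e] = int(np.searchsorted(bps, eps, side="right"))
        c = T - k_seg * eps
        # b vector maps u -> strain: eps = b·u, b = [-axis, +axis]/L0
        dofs = np.concatenate([3 * n0 + np.arange(3), 3 * n1 + np.arange(3)])
        bvec = np.concatenate([-axis, axis]) / L0
        ke = (k_seg * L0) * np.outer(bvec, bvec)
        rows.append(np.repeat(dofs, 6))
        cols.append(np.tile(dofs, 6))
        vals.append(ke.ravel())
        # internal constant force: g_const = c·L0·b moved to the RHS
        f[dofs] -= c * L0 * bvec
    if rows:
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        ).tocsr()
    return K, f, _TrussState(active, segment, strain, tension)


# ------------------------------------------------------------- contact

@dataclass
class ContactState:
    """Per-pair contact state at the converged solution."""

    pair_index: int
    slave_nodes: np.ndarray  # (k,) node ids
    active: np.ndarray  # (k,) bool
    gap: np.ndarray  # (k,) signed gap, mm (negative = penetration)
    normal: np.ndarray  # (k, 3) master outward normal
    normal_force: np.ndarray  # (k, 3) force on slave node, N
    tangential_force: np.ndarray  # (k, 3)
    area: np.ndarray  # (k,) tributary area per slave node, mm²
    tied: bool = False


def _tri_closest_point(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Closest point on triangle abc to p; returns (point, barycentric weights)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a, np.array([1.0, 0.0, 0.0])
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b, np.array([0.0, 1.0, 0.0])
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return a + v * ab, np.array([1 - v, v, 0.0])
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c, np.array([0.0, 0.0, 1.0])
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return a + w * ac, np.array([1 - w, 0.0, w])
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b), np.array([0.0, 1 - w, w])
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return a + v * ab + w * ac, np.array([1 - v - w, v, w])


class _PairGeometry:
    """Frozen (per outer iteration) node-to-surface projection for one pair."""

    def __init__(self, mesh: Mesh, pair, materials: MaterialField, part_E: dict):
        self.pair = pair
        self.slave = np.asarray(mesh.node_sets[pair.slave_nodes], dtype=int)
        self.facets = np.asarray(mesh.facet_sets[pair.master_facets], dtype=int)
        # tributary area per slave node from the slave-side facet set when one
        # exists with the conventional "<name>_facets" companion; otherwise
        # approximate by master facet areas at projection time.
        comp = pair.slave_nodes.replace("_nodes", "_facets")
        self.slave_facets = np.asarray(mesh.facet_sets.get(comp, []), dtype=int).reshape(-1, 3)
        self.area = _tributary_area(mesh, self.slave, self.slave_facets, self.facets)
        if pair.penalty is not None:
            self.k = float(pair.penalty) * np.ones(len(self.slave))
        else:
            # 100 × softer neighbour's modulus per unit tributary area per mm
            E_soft = part_E.get(pair.slave_nodes, 20.0)
            self.k = 100.0 * E_soft * np.maximum(self.area, 1e-6)
        self.cache = None  # (fidx, weights, normal) once the pairing is frozen

    def project(self, coords: np.ndarray, frozen: bool = False):
        """Project slave nodes onto the master surface at given coordinates.

        Returns (gap, normal, facet_idx, weights). With ``frozen`` and a
        cached pairing, only the gaps are re-evaluated along the cached
        normals — re-pairing mid-iteration between near-equidistant facets
        (a slave node sliding over a shared master vertex) otherwise produces
        persistent micro-oscillations of the fixed point.
        """
        if frozen and self.cache is not None:
            fidx, weights, normal = self.cache
            q = np.einsum("ij,ijk->ik", weights, coords[self.facets[fidx]])
            gap = np.einsum("ij,ij->i", coords[self.slave] - q, normal)
            return gap, normal, fidx, weights
        tri_pts = coords[self.facets]
        centroids = tri_pts.mean(axis=1)
        tree = cKDTree(centroids)
        k = min(8, len(self.facets))
        _, cand = tree.query(coords[self.slave], k=k)
        cand = np.atleast_2d(cand.reshape(len(self.slave), -1))
        gap = np.empty(len(self.slave))
        normal = np.empty((len(self.slave), 3))
        fidx = np.empty(len(self.slave), dtype=int)
        weights = np.empty((len(self.slave), 3))
        for i, s in enumerate(self.slave):
            p = coords[s]
            best = (np.inf, None)
            for f in cand[i]:
                a, b, c = tri_pts[f]
                q, w = _tri_closest_point(p, a, b, c)
                d2 = float((p - q) @ (p - q))
                if d2 < best[0]:
                    nvec = np.cross(b - a, c - a)
                    nn = np.linalg.norm(nvec)
                    best = (d2, (q, w, nvec / nn, f))
            q, w, nvec, f = best[1]
            g = float((p - q) @ nvec)
            gap[i] = g
            normal[i] = nvec
            fidx[i] = f
            weights[i] = w
        self.cache = (fidx, weights, normal)
        return gap, normal, fidx, weights


def _tributary_area(mesh: Mesh, slave: np.ndarray, slave_facets: np.ndarray, master_facets: np.ndarray) -> np.ndarray:
    facets = slave_facets if len(slave_facets) else master_facets
    areas = mesh.tri_areas(facets)
    acc = np.zeros(mesh.n_nodes)
    for tri, a in zip(facets, areas):
        acc[tri] += a / 3.0
    out = acc[slave]
    if len(slave_facets) == 0:
        # fall back: share mean facet area
        out = np.where(out > 0, out, areas.mean() if len(areas) else 1.0)
    return out


# ------------------------------------------------------------- result

@dataclass
class SolveResult:
    """Converged solution fields."""

    u: np.ndarray  # (n, 3) nodal displacements, mm
    tet_stress: np.ndarray  # (m, 3, 3) MPa
    tri_stress: np.ndarray  # (s, 3, 3) membrane stress, MPa
    truss_tension: np.ndarray  # (t,) N
    truss_strain: np.ndarray
    contact: list  # list[ContactState]
    reactions: np.ndarray  # (n, 3), nonzero at constrained nodes, N
    applied_forces: np.ndarray  # (n, 3) external loads, N
    iterations: int = 0
    converged: bool = False
    residual: float = np.nan
    log: list = field(default_factory=list)

    def equilibrium_residual(self) -> float:
        """‖Σ reactions + Σ applied loads‖ / ‖Σ applied loads‖."""
        total_applied = self.applied_forces.sum(axis=0)
        imbalance = self.reactions.sum(axis=0) + total_applied
        denom = np.linalg.norm(total_applied)
        if denom == 0:
            return float(np.linalg.norm(imbalance))
        return float(np.linalg.norm(imbalance) / denom)


# ------------------------------------------------------------- main solve

def solve_static(
    model: KneeModel,
    materials: MaterialField,
    bcs: BoundaryConditions,
    loads: np.ndarray | None = None,
    method: str = "sparse",
    max_iter: int = 100,
    tol: float = 1e-8,
    contact_seed_distance: float = 0.5,
    stabilization: float = 1e-4,
    step_limit: float = 0.5,
) -> SolveResult:
    """Solve the quasi-static boundary-value problem.

    Parameters
    ----------
    loads : (n, 3) array or None
        External nodal forces; ``None`` builds them from the model's load case.
    method : "sparse" | "dense"
        Linear-algebra backend; dense is a brute-force check path for small
        systems.
    contact_seed_distance : mm
        On the first iteration, contact constraints within this positive gap
        are seeded active so that parts supported only through contact are not
        initially floating.
    stabilization : N/mm
        Weak grounding springs used during the iterations only; the final
        solve runs without them.
    step_limit : mm
        Trust-region cap on the displacement increment per outer iteration.
        Parts supported only through contact would otherwise overshoot the
        gap closure by orders of magnitude and bounce on the penalty springs;
        capping the increment closes gaps progressively. Convergence is only
        declared on an uncapped step.
    """
    mesh = model.mesh
    n = 3 * mesh.n_nodes
    if loads is None:
        loads = build_external_forces(model)
    f_ext = np.asarray(loads, dtype=float).reshape(n)

    K_lin = _assemble_tets(mesh, materials) + _assemble_shells(mesh, model.shell_props)

    part_E = _pair_soft_modulus(mesh, materials, model.contact_pairs)
    pair_geo = [
        _PairGeometry(mesh, pair, materials, part_E) for pair in model.contact_pairs
    ]

    fixed_dofs = bcs.dofs
    fixed_vals = bcs.values
    free = np.setdiff1d(np.arange(n), fixed_dofs)
    if len(fixed_dofs) == 0:
        raise SolverError("no boundary conditions: system is under-constrained")

    u = np.zeros(n)
    u[fixed_dofs] = fixed_vals
    prev_sets = None
    log = []
    converged = False
    it = 0
    last_du = np.inf
    freeze = False  # latch contact pairing once the active sets stabilise

    for it in range(1, max_iter + 1):
        seed = contact_seed_distance if it == 1 else 0.0
        K_t, f_t, t_state = _truss_system(mesh, model.truss_laws, u)
        K_c, f_c, c_states, c_sets = _contact_system(
            mesh, model.truss_laws, pair_geo, u, seed, freeze=freeze
        )
        K = K_lin + K_t + K_c
        if stabilization > 0:
            K = K + stabilization * sp.identity(n, format="csr")
        f = f_ext + f_t + f_c
        u_new = _linear_solve(K, f, free, fixed_dofs, fixed_vals, method)
        step = u_new - u
        du = float(np.max(np.abs(step)))
        capped = step_limit > 0 and du > step_limit
        if capped:
            u = u + step * (step_limit / du)
        else:
            u = u_new
        last_du = du
        sets = (tuple(t_state.active.tolist()), tuple(t_state.segment.tolist()), c_sets)
        log.append({"iteration": it, "du_max": du, "capped": capped,
                    "frozen_pairing": freeze,
                    "n_contact_active": int(sum(s.active.sum() for s in c_states)),
                    "n_truss_active": int(t_state.active.sum())})
        if prev_sets is not None and sets == prev_sets and not capped:
            if freeze and du < tol:
                converged = True
                break
            freeze = True
        prev_sets = sets

    if not converged:
        raise NonConvergenceError(
            f"contact/truss fixed point did not converge in {max_iter} iterations "
            f"(last displacement increment {last_du:.3e} mm)",
            residual=last_du,
        )

    # final stabilisation-free solve with the converged active sets
    K_t, f_t, t_state = _truss_system(mesh, model.truss_laws, u)
    K_c, f_c, c_states, _ = _contact_system(mesh, model.truss_laws, pair_geo, u, 0.0, freeze=True)
    K = K_lin + K_t + K_c
    f = f_ext + f_t + f_c
    u = _linear_solve(K, f, free, fixed_dofs, fixed_vals, method)
    # refresh state at the final displacement
    K_t, f_t, t_state = _truss_system(mesh, model.truss_laws, u)
    K_c, f_c, c_states, _ = _contact_system(mesh, model.truss_laws, pair_geo, u, 0.0, freeze=True)
    K = K_lin + K_t + K_c
    f = f_ext + f_t + f_c

    residual_vec = K @ u - f
    reactions = np.zeros(n)
    reactions[fixed_dofs] = residual_vec[fixed_dofs]

    uu = u.reshape(-1, 3)
    tet_stress = _recover_tet_stress(mesh, materials, uu)
    tri_stress = _recover_shell_stress(mesh, model.shell_props, uu)

    result = SolveResult(
        u=uu,
        tet_stress=tet_stress,
        tri_stress=tri_stress,
        truss_tension=t_state.tension,
        truss_strain=t_state.strain,
        contact=c_states,
        reactions=reactions.reshape(-1, 3),
        applied_forces=f_ext.reshape(-1, 3),
        iterations=it,
        converged=True,
        residual=float(np.max(np.abs(residual_vec[free]))) if len(free) else 0.0,
        log=log,
    )
    return result


def _pair_soft_modulus(mesh: Mesh, materials: MaterialField, pairs) -> dict:
    """Median modulus of the softer part adjoining each pair's slave set."""
    out = {}
    parts = mesh.tet_part.astype(str)
    for pair in pairs:
        slave = np.asarray(mesh.node_sets[pair.slave_nodes], dtype=int)
        sset = set(slave.tolist())
        touching = [
            float(np.median(materials.E[parts == p]))
            for p in np.unique(parts)
            if sset & set(mesh.tets[parts == p].ravel().tolist())
        ]
        out[pair.slave_nodes] = min(touching) if touching else 20.0
    return out


def _contact_system(mesh, laws, pair_geo, u, seed_distance, freeze=False):
    n = 3 * mesh.n_nodes
    uu = u.reshape(-1, 3)
    coords = mesh.points + uu
    rows, cols, vals = [], [], []
    f = np.zeros(n)
    states = []
    set_keys = []
    for gi, geo in enumerate(pair_geo):
        pair = geo.pair
        if pair.tied:
            # reference-configuration pairing, evaluated once
            gap, normal, fidx, w = geo.project(mesh.points, frozen=True)
        else:
            gap, normal, fidx, w = geo.project(coords, frozen=freeze)
        kvec = geo.k
        active = np.zeros(len(geo.slave), dtype=bool)
        # 0 = inactive, 1 = stick, 2 = slip (part of the fixed-point state)
        status = np.zeros(len(geo.slave), dtype=int)
        nforce = np.zeros((len(geo.slave), 3))
        tforce = np.zeros((len(geo.slave), 3))
        for i, s in enumerate(geo.slave):
            tri = geo.facets[fidx[i]]
            wi = w[i]
            nv = normal[i]
            k = kvec[i]
            dofs_s = 3 * s + np.arange(3)
            dofs_m = (3 * tri[:, None] + np.arange(3)).ravel()
            dofs = np.concatenate([dofs_s, dofs_m])
            urel = uu[s] - wi @ uu[tri]
            # M maps element dofs to the slave-master relative displacement
            M = np.zeros((3, 12))
            M[:, :3] = np.eye(3)
            for a in range(3):
                M[:, 3 + 3 * a : 6 + 3 * a] = -wi[a] * np.eye(3)
            if pair.tied:
                active[i] = True
                ke = k * M.T @ M  # bonded in all three axes
                rows.append(np.repeat(dofs, 12))
                cols.append(np.tile(dofs, 12))
                vals.append(ke.ravel())
                nforce[i] = -k * urel
                continue
            if gap[i] >= (seed_distance if seed_distance > 0 else 0.0):
                continue
            active[i] = True
            # normal penalty: energy 0.5 k (g0 + n·(Δu_rel))², Δ relative to current u
            g0 = gap[i] - float(nv @ urel)
            d = np.zeros(12)
            d[:3] = nv
            d[3:] = (-wi[:, None] * nv).ravel()
            ke = k * np.outer(d, d)
            rows.append(np.repeat(dofs, 12))
            cols.append(np.tile(dofs, 12))
            vals.append(ke.ravel())
            f[dofs] -= k * g0 * d
            fn_mag = k * max(0.0, -gap[i])
            nforce[i] = fn_mag * nv
            # penalty-regularised Coulomb stick-slip as a secant tangential
            # spring: stiffness k while sticking, reduced to μ·|Fn|/|t_rel|
            # once the Coulomb cap is reached, so a slipping node transmits
            # exactly the capped force while staying implicit (and therefore
            # free of explicit-force oscillations).
            if pair.friction > 0 and fn_mag > 0:
                P = np.eye(3) - np.outer(nv, nv)
                t_rel = P @ urel
                t_norm = float(np.linalg.norm(t_rel))
                if k * t_norm <= pair.friction * fn_mag or t_norm <= 1e-14:
                    status[i] = 1
                    k_sec = k
                else:
                    status[i] = 2
                    k_sec = pair.friction * fn_mag / t_norm
                ket = k_sec * M.T @ P @ M
                rows.append(np.repeat(dofs, 12))
                cols.append(np.tile(dofs, 12))
                vals.append(ket.ravel())
                tforce[i] = -k_sec * t_rel
        states.append(
            ContactState(
                pair_index=gi,
                slave_nodes=geo.slave,
                active=active,
                gap=gap,
                normal=normal,
                normal_force=nforce,
                tangential_force=tforce,
                area=geo.area,
                tied=pair.tied,
            )
        )
        # the stick/slip status is continuous through the secant stiffness, so
        # only the active set enters the fixed-point state comparison
        set_keys.append(tuple(active.tolist()))
    if rows:
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
        ).tocsr()
    else:
        K = sp.csr_matrix((n, n))
    return K, f, states, tuple(set_keys)


def _linear_solve(K, f, free, fixed_dofs, fixed_vals, method):
    n = K.shape[0]
    u = np.zeros(n)
    u[fixed_dofs] = fixed_vals
    if len(free) == 0:
        return u
    rhs = f[free] - K[free][:, fixed_dofs] @ fixed_vals
    Kff = K[free][:, free]
    try:
        if method == "dense":
            sol = np.linalg.solve(Kff.toarray(), rhs)
        elif method == "sparse":
            with np.errstate(all="ignore"):
                sol = spla.spsolve(Kff.tocsc(), rhs)
        else:
            raise ValueError(f"unknown method {method!r}")
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        raise SolverError(f"singular stiffness matrix: system is under-constrained ({exc})")
    if not np.all(np.isfinite(sol)):
        raise SolverError("singular stiffness matrix: system is under-constrained")
    # a (near-)singular factorisation can return finite garbage: verify the
    # linear residual before accepting the solution
    resid = np.linalg.norm(Kff @ sol - rhs)
    scale = max(np.linalg.norm(rhs), np.linalg.norm(Kff @ sol), 1e-30)
    if resid > 1e-6 * scale:
        raise SolverError(
            f"singular or ill-conditioned stiffness matrix (relative residual {resid / scale:.2e}): "
            "system is under-constrained"
        )
    u[free] = sol
    return u


def contact_update(model: KneeModel, materials: MaterialField, u: np.ndarray) -> list:
    """Evaluate the contact pairs at a displacement state.

    Returns one :class:`ContactState` per pair: active set (penetrating
    nodes), signed gaps, and the penalty normal/tangential forces. Separated
    nodes carry zero force; tangential forces respect the Coulomb cap
    μ·|normal|; tied pairs are always bonded.
    """
    mesh = model.mesh
    part_E = _pair_soft_modulus(mesh, materials, model.contact_pairs)
    pair_geo = [_PairGeometry(mesh, p, materials, part_E) for p in model.contact_pairs]
    uu = np.asarray(u, dtype=float).reshape(3 * mesh.n_nodes)
    _, _, states, _ = _contact_system(mesh, model.truss_laws, pair_geo, uu, 0.0)
    return states


def _recover_tet_stress(mesh: Mesh, materials: MaterialField, uu: np.ndarray) -> np.ndarray:
    m = len(mesh.tets)
    out = np.zeros((m, 3, 3))
    if m == 0:
        return out
    p = mesh.points[mesh.tets]
    J = p[:, 1:] - p[:, :1]
    invJT = np.linalg.inv(J).transpose(0, 2, 1)
    grads = np.zeros((m, 4, 3))
    grads[:, 1:] = invJT
    grads[:, 0] = -invJT.sum(axis=1)
    ue = uu[mesh.tets]  # (m, 4, 3)
    gradu = np.einsum("maj,mak->mjk", grads, ue)  # (m, 3, 3) = ∇u (d u_k / d x_j)
    strain = 0.5 * (gradu + gradu.transpose(0, 2, 1))
    tr = np.trace(strain, axis1=1, axis2=2)
    E, nu = materials.E, materials.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    out = 2 * mu[:, None, None] * strain
    out[:, np.arange(3), np.arange(3)] += (lam * tr)[:, None]
    return out


def _recover_shell_stress(mesh: Mesh, shell_props: dict, uu: np.ndarray) -> np.ndarray:
    s = len(mesh.tris)
    out = np.zeros((s, 3, 3))
    E = shell_props.get("E", 1000.0)
    nu = shell_props.get("nu", 0.4)
    for i, tri in enumerate(mesh.tris):
        p = mesh.points[tri]
        e1 = p[1] - p[0]
        nvec = np.cross(e1, p[2] - p[0])
        A2 = np.linalg.norm(nvec)
        if A2 <= 1e-14:
            continue
        nvec = nvec / A2
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(nvec, e1)
        xy = np.column_stack([(p - p[0]) @ e1, (p - p[0]) @ e2])
        x, y = xy[:, 0], xy[:, 1]
        b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
        c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
        A = A2 / 2.0
        ul = np.column_stack([uu[tri] @ e1, uu[tri] @ e2])
        exx = float(b @ ul[:, 0]) / (2 * A)
        eyy = float(c @ ul[:, 1]) / (2 * A)
        gxy = float(c @ ul[:, 0] + b @ ul[:, 1]) / (2 * A)
        fac = E / (1 - nu**2)
        sxx = fac * (exx + nu * eyy)
        syy = fac * (eyy + nu * exx)
        sxy = fac * (1 - nu) / 2 * gxy
        # embed local plane-stress tensor back into global axes
        P = np.vstack([e1, e2])
        sloc = np.array([[sxx, sxy], [sxy, syy]])
        out[i] = P.T @ sloc @ P
    return out
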