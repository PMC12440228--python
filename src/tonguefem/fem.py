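"""Nonlinear TET10 finite-element machinery (total-Lagrangian).

Assembles internal forces and consistent tangents for Yeoh / Saint
Venant-Kirchhoff materials with superposed Hill-type active fiber stress,
gravity, linear spring attachments and frictionless penalty contact against
rigid triangulated surfaces.  Works internally in SI units (m, Pa, kg, s);
the public mesh API is in millimeters and conversion happens here.

Solvers: Newton-Raphson statics with incremental load stepping and step
halving, and Newmark-beta (or backward-Euler) implicit dynamics with
consistent mass and Rayleigh damping.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import tet10
from .constitutive import (HillActivation, LinearMaterial, YeohMaterial,
                           active_pk2_and_tangent, pk2_and_tangent)
from .mesh import Mesh

MM = 1e-3  # mm -> m


@dataclass
class ActiveMuscle:
    """Per-muscle active-element data prepared for assembly."""
    name: str
    elements: np.ndarray          # (k,) element ids
    fibers: np.ndarray            # (k, 3) reference unit fiber directions
    hill: HillActivation
    base_stress: np.ndarray = None  # (k,) sigma_max*a*f_v, Pa (set per step)
    lam_prev: np.ndarray = None     # (k,) fiber stretch at last step

    def __post_init__(self):
        k = len(self.elements)
        if self.base_stress is None:
            self.base_stress = np.zeros(k)
        if self.lam_prev is None:
            self.lam_prev = np.ones(k)


@dataclass
class Spring:
    """Linear spring from each node of a set to a fixed anchor.

    With ``muscle`` set, the spring is an activation-scaled contractile
    cable: its force is multiplied by ``scale`` (the muscle activation,
    updated by the solver each step) instead of the external load factor.
    """
    nodes: np.ndarray             # node ids
    anchor: np.ndarray            # (3,) anchor point, meters
    stiffness: float              # N/m per node
    muscle: str | None = None
    scale: float = 1.0


@dataclass
class RigidContact:
    vertices: np.ndarray          # (V, 3) meters
    triangles: np.ndarray         # (T, 3)
    penalty: float                # N/m per node
    nodes: np.ndarray             # candidate mesh node ids

    def __post_init__(self):
        from scipy.spatial import cKDTree
        tri = self.vertices[self.triangles]
        self._centroids = tri.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        self._normals = n / np.linalg.norm(n, axis=1, keepdims=True)


def _closest_point_on_triangle(p, a, b, c):
    """Closest point on triangle abc to p (single point, 3-vectors)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return a + ab * v + ac * w


class FEProblem:
    """Discretized problem: precomputed element data + load model.

    Parameters use mm / N/mm at the API boundary (matching the mesh units)
    and are converted to SI internally.
    """

    def __init__(self, mesh: Mesh, material, muscles: list[ActiveMuscle] = (),
                 gravity=(0.0, -9.81, 0.0), springs=(), contacts=(),
                 quadrature_order: int = 2, body_force=None):
        self.mesh = mesh
        self.material = material
        self.muscles = list(muscles)
        self.gravity = np.asarray(gravity, dtype=float)
        self.springs = list(springs)
        self.contacts = list(contacts)

        self.X = mesh.node_coords * MM               # (N, 3) meters
        self.conn = mesh.tet10_connectivity
        self.n_nodes = mesh.n_nodes
        self.n_dof = 3 * self.n_nodes

        pts, w = tet10.quadrature(quadrature_order)
        dN = tet10.shape_gradients(pts)              # (Q, 10, 3)
        Xe = self.X[self.conn]                       # (E, 10, 3)
        Jmat = np.einsum("eai,qaj->eqij", Xe, dN)    # dX/dxi
        detJ = np.linalg.det(Jmat)
        if np.any(detJ <= 0):
            raise ValueError("non-positive Jacobian in reference mesh")
        Jinv = np.linalg.inv(Jmat)
        self.dNdX = np.einsum("qaj,eqji->eqai", dN, Jinv)   # (E, Q, 10, 3)
        self.wdet = w[None, :] * detJ                # (E, Q)

        # DOF scatter indices for element matrices (E, 30)
        edof = (3 * self.conn[:, :, None] + np.arange(3)[None, None, :])
        self.edof = edof.reshape(-1, 30)
        self.krows = np.repeat(self.edof, 30, axis=1).ravel()
        self.kcols = np.tile(self.edof, (1, 30)).ravel()

        # consistent gravity load (constant): f_a = rho * g * int N_a dV
        rho = getattr(material, "density", 1040.0)
        Nint = tet10.reference_mass_integrals().sum(axis=1)  # int N_a over ref tet
        vol6 = np.abs(np.linalg.det(
            np.stack([Xe[:, 1] - Xe[:, 0], Xe[:, 2] - Xe[:, 0],
                      Xe[:, 3] - Xe[:, 0]], axis=1)))        # 6V per element
        fg = np.zeros((self.n_nodes, 3))
        contrib = rho * np.einsum("e,a,j->eaj", vol6, Nint, self.gravity)
        np.add.at(fg, self.conn, contrib)
        if body_force is not None:
            # consistent load for a spatial body-force field f(x) [N/m^3],
            # integrated with a degree-5 rule
            pts5, w5 = tet10.quadrature(5)
            N5 = tet10.shape_functions(pts5)          # (Q5, 10)
            xq = np.einsum("qa,eai->eqi", N5, Xe)     # (E, Q5, 3) meters
            fq = np.apply_along_axis(body_force, -1, xq)  # (E, Q5, 3)
            J5 = np.einsum("eai,qaj->eqij", Xe, tet10.shape_gradients(pts5))
            det5 = np.linalg.det(J5)
            contrib = np.einsum("eq,qa,eqj->eaj", w5[None, :] * det5, N5, fq)
            np.add.at(fg, self.conn, contrib)
        self.f_gravity = fg.ravel()                  # N, at full load

        self._mass = None
        self._muscle_el_index = [
            {"els": np.asarray(m.elements, dtype=np.int64),
             "m0": np.asarray(m.fibers, dtype=float)} for m in self.muscles]

    # ------------------------------------------------------------- mass
    def mass_matrix(self) -> sp.csr_matrix:
        if self._mass is None:
            rho = getattr(self.material, "density", 1040.0)
            Mref = tet10.reference_mass_integrals()  # over ref tet (6V=1)
            Xe = self.X[self.conn]
            vol6 = np.abs(np.linalg.det(
                np.stack([Xe[:, 1] - Xe[:, 0], Xe[:, 2] - Xe[:, 0],
                          Xe[:, 3] - Xe[:, 0]], axis=1)))
            Me = rho * vol6[:, None, None] * Mref[None, :, :]   # (E, 10, 10)
            Ke = np.einsum("eab,ij->eaibj", Me, np.eye(3)).reshape(-1, 900)
            M = sp.coo_matrix((Ke.ravel(), (self.krows, self.kcols)),
                              shape=(self.n_dof, self.n_dof)).tocsr()
            self._mass = M
        return self._mass

    # ------------------------------------------------- fiber kinematics
    def fiber_stretches(self, u: np.ndarray) -> list[np.ndarray]:
        """Per-muscle fiber stretches at element centroids (qp-averaged)."""
        ue = u.reshape(-1, 3)[self.conn]
        out = []
        for mi in self._muscle_el_index:
            els, m0 = mi["els"], mi["m0"]
            F = np.eye(3) + np.einsum("eqai,eqaj->eqij",
                                      np.broadcast_to(ue[els][:, None],
                                                      (len(els), self.wdet.shape[1], 10, 3)),
                                      self.dNdX[els])
            lam = np.linalg.norm(np.einsum("eqij,ej->eqi", F, m0), axis=2)
            out.append(lam.mean(axis=1))
        return out

    # --------------------------------------------------------- assembly
    def assemble(self, u: np.ndarray, external_scale: float = 1.0,
                 with_tangent: bool = True):
        """Residual r = f_int - f_ext and tangent K at displacement u (SI).

        Raises FloatingPointError-like ValueError on element inversion.
        """
        E, Q = self.wdet.shape
        ue = u.reshape(-1, 3)[self.conn]             # (E, 10, 3)
        f = np.zeros((self.n_nodes, 3))
        Kdata = np.zeros((E, 30, 30)) if with_tangent else None

        for q in range(Q):
            dNdX = self.dNdX[:, q]                   # (E, 10, 3)
            w = self.wdet[:, q]                      # (E,)
            F = np.eye(3) + np.einsum("eai,eaj->eij", ue, dNdX)
            detF = np.linalg.det(F)
            if np.any(detF <= 0):
                bad = int(np.argmax(detF <= 0))
                raise ElementInversion(bad)
            C = np.einsum("eki,ekj->eij", F, F)
            S, CC = pk2_and_tangent(C, self.material)
            for m, mi in zip(self.muscles, self._muscle_el_index):
                if not np.any(m.base_stress):
                    continue
                els, m0 = mi["els"], mi["m0"]
                Sa, CCa = active_pk2_and_tangent(C[els], m0, m.base_stress,
                                                 state=m.hill)
                S[els] += Sa
                CC[els] += CCa
            P = np.einsum("eik,ekl->eil", F, S)
            np.add.at(f, self.conn,
                      np.einsum("e,eil,eal->eai", w, P, dNdX))
            if with_tangent:
                geo = np.einsum("e,eal,ekl,ebk->eab", w, dNdX, S, dNdX)
                Kdata += np.einsum("eab,ij->eaibj", geo,
                                   np.eye(3)).reshape(E, 30, 30)
                D = np.einsum("eik,eklmn->eilmn", F, CC)
                D2 = np.einsum("eilmn,ejn->eilmj", D, F)
                Kdata += np.einsum("e,eal,eilmj,ebm->eaibj", w, dNdX, D2,
                                   dNdX, optimize=True).reshape(E, 30, 30)

        r = f.ravel() - external_scale * self.f_gravity
        diag_extra = np.zeros(self.n_dof)

        x_cur = self.X + u.reshape(-1, 3)
        for s in self.springs:
            factor = s.scale if s.muscle is not None else external_scale
            d = (s.anchor[None, :] - x_cur[s.nodes]) * factor
            fs = s.stiffness * d
            r.reshape(-1, 3)[s.nodes] -= fs
            diag_extra[(3 * s.nodes[:, None] + np.arange(3)).ravel()] += \
                s.stiffness * factor

        contact_rows = []
        self.contact_active = 0
        for c in self.contacts:
            fc, Kc = self._contact_forces(c, x_cur)
            r -= fc
            if Kc is not None:
                contact_rows.append(Kc)

        if not with_tangent:
            return r, None
        K = sp.coo_matrix((Kdata.ravel(), (self.krows, self.kcols)),
                          shape=(self.n_dof, self.n_dof)).tocsr()
        if diag_extra.any():
            K = K + sp.diags(diag_extra)
        for Kc in contact_rows:
            K = K + Kc
        return r, K

    def _contact_forces(self, c: RigidContact, x_cur):
        f = np.zeros(self.n_dof)
        rows, cols, vals = [], [], []
        pts = x_cur[c.nodes]
        _, cand = c._tree.query(pts, k=min(8, len(c._centroids)))
        cand = np.atleast_2d(cand)
        tri = c.vertices[c.triangles]
        for idx, nid in enumerate(c.nodes):
            p = pts[idx]
            best_d, best_n, best_abs = None, None, np.inf
            for t in np.atleast_1d(cand[idx]):
                a, b, cc_ = tri[t]
                q = _closest_point_on_triangle(p, a, b, cc_)
                dvec = p - q
                dist = np.linalg.norm(dvec)
                sgn = float(np.sign(dvec @ c._normals[t])) or 1.0
                if dist < best_abs:
                    best_abs = dist
                    best_d = sgn * dist
                    best_n = (c._normals[t] if dist < 1e-14
                              else sgn * dvec / dist)
            if best_d is not None and best_d < 0.0:
                self.contact_active += 1
                fn = -c.penalty * best_d * best_n     # push out along normal
                f[3 * nid:3 * nid + 3] += fn
                Kn = c.penalty * np.outer(best_n, best_n)
                for i in range(3):
                    for j in range(3):
                        rows.append(3 * nid + i)
                        cols.append(3 * nid + j)
                        vals.append(Kn[i, j])
        K = sp.coo_matrix((vals, (rows, cols)),
                          shape=(self.n_dof, self.n_dof)).tocsr() if vals else None
        return f, K


class ElementInversion(RuntimeError):
    def __init__(self, element_id: int):
        super().__init__(f"element {element_id} inverted during assembly")
        self.element_id = element_id


# --------------------------------------------------------------- DOF maps
def build_dof_partition(mesh: Mesh, fixed_sets, imposed_sets):
    """Boolean mask of constrained dofs + node id arrays per imposed set.

    A fixed-set entry is either a node-set name (all three components
    fixed) or a ``(name, (fx, fy, fz))`` pair fixing selected components
    only — e.g. ``("midsagittal", (False, False, True))`` for the
    mid-sagittal symmetry condition u_z = 0.
    """
    n_dof = 3 * mesh.n_nodes
    constrained = np.zeros(n_dof, dtype=bool)
    fully_fixed = set()
    for entry in fixed_sets:
        if isinstance(entry, str):
            name, comps = entry, (True, True, True)
        else:
            name, comps = entry
        for nid in np.asarray(mesh.node_sets[name]).ravel():
            if all(comps):
                fully_fixed.add(int(nid))
            for k in range(3):
                if comps[k]:
                    constrained[3 * nid + k] = True
    imposed_nodes = {}
    for name in imposed_sets:
        ids = np.asarray(mesh.node_sets[name]).ravel()
        for nid in ids:
            if int(nid) in fully_fixed:
                raise ValueError(
                    f"node {nid} is both fixed and displacement-driven")
            constrained[3 * nid:3 * nid + 3] = True
        imposed_nodes[name] = ids
    return constrained, imposed_nodes


# ---------------------------------------------------------------- statics
@dataclass
class NewtonOptions:
    tol: float = 1e-6             # relative residual
    abs_tol: float = 1e-10        # N, absolute fallback
    max_iter: int = 60
    max_cuts: int = 8
    #: reuse the LU factorization while the residual contracts at least
    #: this much per iteration (modified Newton); 0 forces full Newton
    reuse_contraction: float = 0.5
    #: cap on the per-iteration displacement increment (m); wild steps
    #: through near-singular tangents are rescaled to this trust radius
    max_increment: float = 0.02
    #: deepest line-search backtracking factor
    min_alpha: float = 1.0 / 256.0


class NonConvergence(RuntimeError):
    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


# --------------------------------------------------------- linear solvers
class DirectSolver:
    """Sparse LU (SuperLU, COLAMD ordering)."""

    def __call__(self, Kff):
        return splu(Kff.tocsc(), permc_spec="COLAMD").solve


def prolongation_matrix(n_parent_nodes: int, new_node_edges: np.ndarray,
                        n_child_nodes: int) -> sp.csr_matrix:
    """Displacement prolongation from a parent mesh onto its red-refined
    child: parent nodes are injected, new midside nodes take the average of
    their edge endpoints.  Shape (3*n_child, 3*n_parent)."""
    rows, cols, vals = [], [], []
    for i in range(3 * n_parent_nodes):
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
    for j, (a, b) in enumerate(np.asarray(new_node_edges)):
        nid = n_parent_nodes + j
        for k in range(3):
            rows += [3 * nid + k, 3 * nid + k]
            cols += [3 * int(a) + k, 3 * int(b) + k]
            vals += [0.5, 0.5]
    return sp.csr_matrix((vals, (rows, cols)),
                         shape=(3 * n_child_nodes, 3 * n_parent_nodes))


class TwoGridSolver:
    """Conjugate gradients preconditioned by an additive two-level scheme:
    damped Jacobi plus a Galerkin coarse-grid correction through the
    red-refinement prolongation.  Falls back to a direct solve if CG fails.

    Built once per refinement step from the full-space prolongation ``P``
    and the free-dof masks of the fine and coarse levels.
    """

    def __init__(self, P: sp.spmatrix, fine_free: np.ndarray,
                 coarse_free: np.ndarray, omega: float = None,
                 tol: float = 1e-7, maxiter: int = 1200):
        self.Pf = P.tocsr()[fine_free][:, coarse_free].tocsr()
        self.omega = omega    # None: auto-scale from lam_max(D^-1 K)
        self.tol = tol
        self.maxiter = maxiter
        self.iterations: list[int] = []

    def __call__(self, Kff):
        from scipy.sparse.linalg import LinearOperator, cg
        Kff = Kff.tocsr()
        diag = Kff.diagonal()
        omega = self.omega
        if omega is None:
            # Jacobi weight must satisfy omega < 2 / lam_max(D^-1 K) for
            # the smoother (and hence the preconditioner) to stay SPD;
            # estimate lam_max by power iteration
            rng = np.random.default_rng(0)
            x = rng.standard_normal(Kff.shape[0])
            lam = 1.0
            for _ in range(10):
                x = (Kff @ x) / diag
                lam = np.linalg.norm(x)
                x /= lam
            omega = 1.2 / lam
        dinv = omega / diag
        Ac = (self.Pf.T @ Kff @ self.Pf).tocsc()
        lu_c = splu(Ac, permc_spec="COLAMD")
        Pf, PfT = self.Pf, self.Pf.T.tocsr()

        def precond(r):
            # symmetric multiplicative cycle: Jacobi, coarse, Jacobi
            x = dinv * r
            res = r - Kff @ x
            x = x + Pf @ lu_c.solve(PfT @ res)
            res = r - Kff @ x
            return x + dinv * res

        M = LinearOperator(Kff.shape, matvec=precond)

        def solve(b):
            count = [0]
            x, info = cg(Kff, b, rtol=self.tol, atol=0.0,
                         maxiter=self.maxiter, M=M,
                         callback=lambda xk: count.__setitem__(0, count[0] + 1))
            if info != 0:
                x = splu(Kff.tocsc(), permc_spec="COLAMD").solve(b)
            self.iterations.append(count[0])
            return x

        return solve


def newton_solve(problem: FEProblem, u0, constrained, prescribed_values,
                 external_scale: float, opts: NewtonOptions,
                 linear_solver=None):
    """Solve equilibrium at one load level.  Returns (u, residual_norms)."""
    linear_solver = linear_solver or DirectSolver()
    u = u0.copy()
    u[constrained] = prescribed_values[constrained]
    free = ~constrained
    ref = max(np.linalg.norm(problem.f_gravity[free]) * external_scale,
              opts.abs_tol)
    norms = []
    lu = None
    r, _ = problem.assemble(u, external_scale, with_tangent=False)
    rn = np.linalg.norm(r[free])
    for it in range(opts.max_iter):
        norms.append(rn)
        if not np.isfinite(rn):
            raise NonConvergence("non-finite residual", {"norms": norms})
        if it == 0:
            ref = max(ref, rn)
        if rn <= opts.tol * max(ref, opts.abs_tol) or rn <= opts.abs_tol:
            return u, norms
        refresh = lu is None or (len(norms) >= 2 and
                                 rn > opts.reuse_contraction * norms[-2])
        if refresh:
            _, K = problem.assemble(u, external_scale)
            lu = linear_solver(K[free][:, free])
        du = lu(-r[free])
        step = np.abs(du).max()
        if step > opts.max_increment:  # trust-radius cap on wild steps
            du *= opts.max_increment / step
        # strict-decrease backtracking (also guards against inversion)
        alpha, accepted = 1.0, False
        while alpha >= opts.min_alpha:
            u_try = u.copy()
            u_try[free] += alpha * du
            try:
                r_try, _ = problem.assemble(u_try, external_scale,
                                            with_tangent=False)
                rn_try = np.linalg.norm(r_try[free])
            except ElementInversion:
                alpha *= 0.5
                continue
            if np.isfinite(rn_try) and rn_try < rn:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            raise NonConvergence(
                f"line search failed at iteration {it}", {"norms": norms})
        u, r, rn = u_try, r_try, rn_try
        if alpha < 1.0:
            lu = None  # stale tangent after a damped step: refactor next
    raise NonConvergence(f"Newton did not converge in {opts.max_iter} "
                         f"iterations (residual {norms[-1]:.3e})",
                         {"norms": norms})
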