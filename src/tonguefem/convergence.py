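"""Mesh-convergence methodology: uniform refinement series under gravity,
landmark displacement errors against the finest mesh, and acceptance
against a displacement-error threshold (default 1 mm, the accuracy of
electromagnetic articulography, which sets the useful resolution for
speech-articulation simulation).

Landmark errors are Euclidean distances (mm) between converged landmark
displacement vectors; landmark nodes are parent vertex nodes and therefore
shared by construction across all red-refinement levels.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fem import NewtonOptions
from .mesh import Mesh
from .phantom import PhantomSpec, generate_tongue_phantom
from .refine import refine_uniform
from .solver import BoundaryConditions, solve_static

LANDMARKS = ("landmark_apical", "landmark_alveolar", "landmark_velar",
             "landmark_pharyngeal")

#: gravity-load boundary conditions: mouth floor plus the bone-bonded
#: hyoid/mandible attachment regions are held fixed
FIXED_SETS = ("floor_fixed", "hyoid_attachment", "mandible_attachment")


@dataclass
class ConvergenceReport:
    node_counts: list                     # per level
    element_counts: list
    mesh_sizes_mm: list                   # mean element size per level
    errors_mm: dict                       # landmark -> list of abs errors
    displacements_mm: dict                # landmark -> list of (3,) vectors
    threshold_mm: float
    selected_level: int | None            # first level with all errors < thr
    failed_levels: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "node_counts": [int(n) for n in self.node_counts],
            "element_counts": [int(n) for n in self.element_counts],
            "mesh_sizes_mm": [float(x) for x in self.mesh_sizes_mm],
            "errors_mm": {k: [float(x) for x in v]
                          for k, v in self.errors_mm.items()},
            "displacements_mm": {k: [list(map(float, d)) for d in v]
                                 for k, v in self.displacements_mm.items()},
            "threshold_mm": self.threshold_mm,
            "selected_level": self.selected_level,
            "failed_levels": self.failed_levels,
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ConvergenceReport":
        doc = json.loads(text)
        return cls(doc["node_counts"], doc["element_counts"],
                   doc["mesh_sizes_mm"], doc["errors_mm"],
                   {k: [np.array(d) for d in v]
                    for k, v in doc["displacements_mm"].items()},
                   doc["threshold_mm"], doc["selected_level"],
                   doc["failed_levels"], doc.get("metadata", {}))

    def save(self, path):
        Path(path).write_text(self.to_json())

    def to_csv(self) -> str:
        names = list(self.errors_mm)
        lines = ["nodes," + ",".join(n.replace("landmark_", "") for n in names)]
        for lvl, n in enumerate(self.node_counts):
            row = [str(int(n))]
            for name in names:
                row.append(f"{self.errors_mm[name][lvl]:.4g}")
            lines.append(",".join(row))
        return "\n".join(lines) + "\n"


def run_convergence(base_spec: PhantomSpec = None, n_levels: int = 4,
                    threshold_mm: float = 1.0, material=None,
                    landmarks=LANDMARKS, load_scale_steps: int = 4,
                    solver=None) -> ConvergenceReport:
    """Gravity-load convergence analysis on a uniform refinement series.

    Generates the level-0 phantom from ``base_spec``, red-refines it
    ``n_levels - 1`` times, solves the static gravity problem on every
    level, and reports per-landmark absolute errors (Euclidean distance of
    the landmark displacement vector) against the finest level, selecting
    the coarsest level with all errors below ``threshold_mm``.

    ``solver`` may replace the static gravity solve (signature
    ``solver(mesh) -> dict landmark -> (3,) displacement mm``), which the
    manufactured-solution tests use.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 refinement levels")
    base_spec = base_spec or PhantomSpec(resolution=16.0)
    meshes = [generate_tongue_phantom(base_spec, require_muscles=False)]
    infos = [None]
    for _ in range(n_levels - 1):
        child, info = refine_uniform(meshes[-1])
        meshes.append(child)
        infos.append(info)

    fixed = list(FIXED_SETS)
    if "midsagittal" in meshes[0].node_sets:
        fixed.append(("midsagittal", (False, False, True)))
    fixed = tuple(fixed)

    disp = {n: [] for n in landmarks}
    failed = []
    u_prev = None
    for lvl, mesh in enumerate(meshes):
        try:
            if solver is not None:
                d = solver(mesh)
                for n in landmarks:
                    disp[n].append(np.asarray(d[n], dtype=float))
                continue
            guess, linsolve = None, None
            if u_prev is not None:
                # warm start: inject the coarser solution and average it
                # onto the new midside nodes
                edges = infos[lvl]["new_node_edges"]
                up = u_prev.reshape(-1, 3)
                guess = np.vstack([up, 0.5 * (up[edges[:, 0]] + up[edges[:, 1]])])
                if mesh.n_nodes > 12000:
                    from .fem import (TwoGridSolver, build_dof_partition,
                                      prolongation_matrix)
                    P = prolongation_matrix(meshes[lvl - 1].n_nodes, edges,
                                            mesh.n_nodes)
                    fine_c, _ = build_dof_partition(mesh, fixed, [])
                    coarse_c, _ = build_dof_partition(meshes[lvl - 1],
                                                      fixed, [])
                    linsolve = TwoGridSolver(P, ~fine_c, ~coarse_c)
            res = solve_static(mesh, material=material, muscles=[],
                               bc=BoundaryConditions(fixed_sets=fixed),
                               load_scale_steps=load_scale_steps,
                               options=NewtonOptions(),
                               initial_guess=guess, linear_solver=linsolve)
            u_prev = res.final_displacement
            for n in landmarks:
                disp[n].append(np.asarray(res.landmark_final(n), dtype=float))
        except Exception as err:  # partial results with failure flag
            failed.append({"level": lvl, "error": str(err)})
            for n in landmarks:
                disp[n].append(None)
            u_prev = None
            continue

    errors = {n: [] for n in landmarks}
    ref_ok = all(disp[n][-1] is not None for n in landmarks)
    for n in landmarks:
        ref = disp[n][-1]
        for lvl in range(n_levels):
            if disp[n][lvl] is None or not ref_ok:
                errors[n].append(float("nan"))
            else:
                errors[n].append(float(np.linalg.norm(disp[n][lvl] - ref)))

    selected = None
    for lvl in range(n_levels):
        vals = [errors[n][lvl] for n in landmarks]
        if all(np.isfinite(v) and v < threshold_mm for v in vals):
            selected = lvl
            break

    return ConvergenceReport(
        node_counts=[m.n_nodes for m in meshes],
        element_counts=[m.n_elements for m in meshes],
        mesh_sizes_mm=[float(m.mean_edge_lengths().mean()) for m in meshes],
        errors_mm=errors,
        displacements_mm={n: [d if d is not None else np.full(3, np.nan)
                              for d in disp[n]] for n in landmarks},
        threshold_mm=threshold_mm,
        selected_level=selected,
        failed_levels=failed,
        metadata={"n_levels": n_levels,
                  "spec_resolution_mm": base_spec.resolution},
    )


def _box_mesh(n: int, size_mm: float = 10.0) -> Mesh:
    """Structured TET10 box on [0, size]^3 with n cells per edge (Kuhn
    triangulation); defines a 'boundary' node set."""
    from .mesh import promote_tet4
    from .phantom import _KUHN_TETS, _corner_ids

    grid = np.linspace(0.0, size_mm, n + 1)
    X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tets = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                cid = _corner_ids(i, j, k, n, n, n)
                for t in _KUHN_TETS:
                    tets.append([cid[t[0]], cid[t[1]], cid[t[2]], cid[t[3]]])
    coords, conn = promote_tet4(nodes, np.array(tets, dtype=np.int64))
    mesh = Mesh(coords, conn)
    v = mesh.volumes()
    flip = np.where(v < 0)[0]
    if flip.size:
        conn[flip] = conn[flip][:, [0, 2, 1, 3, 6, 5, 4, 7, 9, 8]]
        mesh = Mesh(coords, conn)
    eps = 1e-9
    on_b = np.any((np.abs(coords) < eps)
                  | (np.abs(coords - size_mm) < eps), axis=1)
    mesh.node_sets["boundary"] = np.where(on_b)[0]
    return mesh


def manufactured_solution_study(n_levels: int = 3, n0: int = 2,
                                size_mm: float = 10.0,
                                young: float = 1e4, poisson: float = 0.3,
                                amplitude_mm: float = 5e-3) -> ConvergenceReport:
    """Method-of-manufactured-solutions oracle for the displacement solver.

    A divergence-free displacement field
    u = A (sin(pi y/L), sin(pi z/L), sin(pi x/L)) on a cube, with the
    matching linear-elastic body force f = mu (pi/L)^2 u and exact Dirichlet
    values on the boundary, is solved on a nested refinement series; the
    report carries H1-seminorm errors against the exact field (expected
    convergence rate for quadratic tetrahedra: 2).
    """
    from .constitutive import LinearMaterial
    from .fem import (FEProblem, NewtonOptions, build_dof_partition,
                      newton_solve)
    from . import tet10 as _t10

    L = size_mm * 1e-3                     # meters
    A = amplitude_mm * 1e-3
    k = np.pi / L
    mat = LinearMaterial(young_modulus=young, poisson_ratio=poisson,
                         density=1000.0)
    mu = mat.lame[1]

    def u_exact(x):  # x in meters -> displacement in meters
        return A * np.stack([np.sin(k * x[..., 1]), np.sin(k * x[..., 2]),
                             np.sin(k * x[..., 0])], axis=-1)

    def grad_exact(x):  # (..., 3, 3), du_i/dx_j
        g = np.zeros(x.shape[:-1] + (3, 3))
        g[..., 0, 1] = A * k * np.cos(k * x[..., 1])
        g[..., 1, 2] = A * k * np.cos(k * x[..., 2])
        g[..., 2, 0] = A * k * np.cos(k * x[..., 0])
        return g

    def body_force(x):
        return mu * k * k * u_exact(x)

    meshes = [_box_mesh(n0, size_mm)]
    for _ in range(n_levels - 1):
        child, _ = refine_uniform(meshes[-1])
        meshes.append(child)

    errors, sizes = [], []
    for mesh in meshes:
        problem = FEProblem(mesh, mat, gravity=(0, 0, 0),
                            body_force=body_force)
        constrained, _ = build_dof_partition(mesh, ["boundary"], [])
        pres = u_exact(problem.X).ravel()
        u, _ = newton_solve(problem, np.zeros(problem.n_dof), constrained,
                            pres, 1.0, NewtonOptions(tol=1e-10))
        # H1 seminorm of the error by quadrature
        pts, w = _t10.quadrature(4)
        dN = _t10.shape_gradients(pts)
        Xe = problem.X[problem.conn]
        J = np.einsum("eai,qaj->eqij", Xe, dN)
        detJ = np.linalg.det(J)
        dNdX = np.einsum("qaj,eqji->eqai", dN, np.linalg.inv(J))
        ue = u.reshape(-1, 3)[problem.conn]
        grad_h = np.einsum("eai,eqaj->eqij", ue, dNdX)
        xq = np.einsum("qa,eai->eqi", _t10.shape_functions(pts), Xe)
        diff = grad_h - grad_exact(xq)
        err2 = np.einsum("eq,eqij->", w[None, :] * detJ, diff ** 2)
        errors.append(float(np.sqrt(err2)))
        sizes.append(float(mesh.mean_edge_lengths().mean()))

    return ConvergenceReport(
        node_counts=[m.n_nodes for m in meshes],
        element_counts=[m.n_elements for m in meshes],
        mesh_sizes_mm=sizes,
        errors_mm={"mms": errors},
        displacements_mm={},
        threshold_mm=float("nan"),
        selected_level=None,
        metadata={"study": "manufactured solution, H1-seminorm errors",
                  "expected_rate": 2.0},
    )


def convergence_order(report: ConvergenceReport, landmark: str) -> float:
    """Least-squares slope of log(error) vs log(h) for one landmark.

    The reference (zero-error) level is excluded.  Raises on degenerate
    spacing (identical mesh sizes); returns 0.0 for stagnating (all-equal)
    errors.
    """
    errs = np.asarray(report.errors_mm[landmark], dtype=float)
    h = np.asarray(report.mesh_sizes_mm, dtype=float)
    mask = np.isfinite(errs) & (errs > 0.0)
    errs, h = errs[mask], h[mask]
    if errs.size < 2:
        raise ValueError("need at least 2 nonzero-error levels for a rate")
    if np.ptp(h) < 1e-12 * h.mean():
        raise ValueError("degenerate spacing: identical mesh sizes")
    if np.ptp(errs) < 1e-14 * max(errs.max(), 1e-300):
        return 0.0  # stagnation
    slope, _ = np.polyfit(np.log(h), np.log(errs), 1)
    return float(slope)
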