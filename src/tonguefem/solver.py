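"""Quasi-static and transient muscle-driven simulation of TET10 soft-tissue
meshes.

`solve_static` runs Newton-Raphson equilibrium under gravity, imposed
displacements, spring attachments and Hill-type muscle activation, with
incremental load stepping (all loads scaled together) and step halving on
divergence.  `solve_transient` integrates the same model in time with
consistent mass, Rayleigh damping and an implicit Newmark-beta (default
beta = 1/4, gamma = 1/2) or backward-Euler scheme, evaluating piecewise
linear activation schedules per step; a steady-state detector reports when
the kinetic energy has decayed, giving the held posture.

`apply_phoneme_preset` builds the activation schedules and jaw/hyoid
boundary conditions for the five preset phonemes /a/, /u/, /i/, /t/, /k/.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .constitutive import YeohMaterial
from .fem import (MM, ActiveMuscle, ElementInversion, FEProblem,
                  NewtonOptions, NonConvergence, RigidContact, Spring,
                  build_dof_partition, newton_solve)
from .mesh import Mesh
from .muscles import (ActivationSchedule, MuscleSet, jaw_hyoid_displacements,
                      muscle_sets_from_mesh, schedule_from_table)


@dataclass
class BoundaryConditions:
    """Fixed sets, imposed displacement trajectories, gravity and springs.

    ``imposed`` maps a node-set name to piecewise-linear breakpoints
    [(t_s, (dx, dy, dz) mm), ...]; trajectories must start at zero
    displacement.  ``springs`` are (node_set, anchor_point_mm, stiffness
    N/mm) triples standing in for 1D cable muscles.  A node may not be both
    fixed and displacement-driven.
    """
    fixed_sets: tuple = ("floor_fixed",)
    imposed: dict = field(default_factory=dict)
    gravity: tuple = (0.0, -9.81, 0.0)       # m/s^2
    springs: list = field(default_factory=list)

    def validate(self):
        for name, traj in self.imposed.items():
            if not traj:
                raise ValueError(f"empty trajectory for {name}")
            t0, d0 = traj[0]
            if np.linalg.norm(d0) > 1e-12:
                raise ValueError(
                    f"trajectory for {name} must start at zero displacement")

    def trajectory_at(self, name: str, t: float) -> np.ndarray:
        traj = self.imposed[name]
        times = np.array([p[0] for p in traj])
        vals = np.array([p[1] for p in traj], dtype=float)
        return np.array([np.interp(t, times, vals[:, k]) for k in range(3)])

    def final_displacement(self, name: str) -> np.ndarray:
        return np.asarray(self.imposed[name][-1][1], dtype=float)


@dataclass
class ContactSurface:
    """Rigid triangulated obstacle (mm) with a frictionless penalty."""
    vertices: np.ndarray          # (V, 3) mm
    triangles: np.ndarray         # (T, 3) int
    penalty: float                # N/mm per node
    node_set: str | None = None   # candidate mesh nodes; default: surface nodes

    def validate(self):
        if self.penalty <= 0:
            raise ValueError("contact penalty must be positive")


@dataclass
class SimulationResult:
    times: np.ndarray                     # (T,) s
    displacements: np.ndarray             # (T, N, 3) mm
    landmark_trajectories: dict           # name -> (T, 3) mm
    element_J: np.ndarray                 # (T, E) det F history
    residual_norms: list                  # per step: list of Newton norms
    contact_active: list                  # per step: active contact count
    converged: bool = True
    steady_state_index: int | None = None
    kinetic_energy: np.ndarray = None     # (T,) J (transient only)
    diagnostics: dict = field(default_factory=dict)

    @property
    def final_displacement(self) -> np.ndarray:
        return self.displacements[-1]

    def landmark_final(self, name: str) -> np.ndarray:
        return self.landmark_trajectories[name][-1]


# -------------------------------------------------------------- helpers
def _build_problem(mesh: Mesh, material, muscles, bc: BoundaryConditions,
                   contacts=()):
    material = material or YeohMaterial()
    if muscles is None:
        muscles = muscle_sets_from_mesh(mesh)
    act = [ActiveMuscle(m.name, m.element_ids, m.fibers, m.hill)
           for m in muscles]
    springs = []
    for entry in bc.springs:
        node_set, anchor_mm, k_n_per_mm = entry[:3]
        muscle = entry[3] if len(entry) > 3 else None
        springs.append(Spring(np.asarray(mesh.node_sets[node_set]).ravel(),
                              np.asarray(anchor_mm, dtype=float) * MM,
                              k_n_per_mm / MM, muscle=muscle,
                              scale=0.0 if muscle else 1.0))
    rigid = []
    for c in contacts:
        c.validate()
        nodes = (np.asarray(mesh.node_sets[c.node_set]).ravel()
                 if c.node_set else mesh.surface_node_ids())
        rigid.append(RigidContact(np.asarray(c.vertices) * MM,
                                  np.asarray(c.triangles, dtype=np.int64),
                                  c.penalty / MM, nodes))
    problem = FEProblem(mesh, material, act, gravity=bc.gravity,
                        springs=springs, contacts=rigid)
    return problem, act


def _prescribed_vector(mesh, bc, imposed_nodes, t=None, scale=1.0):
    """Constrained-dof displacement values (SI) at time t / final * scale."""
    vals = np.zeros(3 * mesh.n_nodes)
    for name, nids in imposed_nodes.items():
        d = (bc.trajectory_at(name, t) if t is not None
             else bc.final_displacement(name)) * MM * scale
        for nid in nids:
            vals[3 * nid:3 * nid + 3] = d
    return vals

def _element_J(problem: FEProblem, u: np.ndarray) -> np.ndarray:
    ue = u.reshape(-1, 3)[problem.conn]
    F = np.eye(3) + np.einsum("eai,eqaj->eqij", ue, problem.dNdX)
    return np.linalg.det(F).mean(axis=1)


def _landmark_names(mesh: Mesh):
    return [n for n in mesh.node_sets if n.startswith("landmark_")]


def _landmark_disp(mesh: Mesh, u_mm: np.ndarray) -> dict:
    out = {}
    for n in _landmark_names(mesh):
        nid = int(np.asarray(mesh.node_sets[n]).ravel()[0])
        out[n] = u_mm[nid]
    return out


# -------------------------------------------------------------- statics
def solve_static(mesh: Mesh, material=None, muscles=None,
                 bc: BoundaryConditions = None, load_scale_steps: int = 5,
                 schedules: list[ActivationSchedule] = (),
                 contacts=(), options: NewtonOptions = None,
                 record_steps: bool = False, initial_guess=None,
                 linear_solver=None,
                 guess_fallback: bool = True) -> SimulationResult:
    """Static equilibrium under gravity, activation plateaus, springs and
    imposed (final) displacements, via incremental load continuation.

    All loads are ramped together by the continuation factor; activation
    plateaus are taken from the end of each schedule.  Diverged steps are
    halved (up to ``options.max_cuts``); non-convergence after the cut
    budget raises :class:`~tonguefem.fem.NonConvergence` with diagnostics.
    """
    bc = bc or BoundaryConditions()
    bc.validate()
    options = options or NewtonOptions()
    problem, act = _build_problem(mesh, material, muscles, bc, contacts)
    constrained, imposed_nodes = build_dof_partition(
        mesh, bc.fixed_sets, list(bc.imposed))

    plateau = {s.muscle: s.plateau for s in schedules}
    max_total_steps = 12 * max(load_scale_steps, 1)
    total_steps = 0
    u = np.zeros(problem.n_dof)
    base_dscale = 1.0 / max(load_scale_steps, 1)
    scale_done, dscale = 0.0, base_dscale
    if initial_guess is not None:
        # warm start (e.g. interpolated from a coarser mesh): try the full
        # load in one step; fall back to continuation from zero on failure
        u = np.asarray(initial_guess, dtype=float).reshape(-1) * MM
        dscale = 1.0
    cuts = 0
    history, norms_all, contact_all = [], [], []
    times = []
    while scale_done < 1.0 - 1e-12:
        total_steps += 1
        if total_steps > max_total_steps:
            raise NonConvergence(
                f"static continuation exceeded {max_total_steps} steps "
                f"(reached load scale {scale_done:.4f})",
                {"scale": scale_done})
        scale = min(1.0, scale_done + dscale)
        for m in act:
            s_val = plateau.get(m.name, 0.0) * scale
            a_val = s_val / m.hill.sigma_max
            m.hill.activation = min(a_val, 1.0)
            m.base_stress[:] = s_val          # f_v = 1 in statics
        sigma_max = {m.name: m.hill.sigma_max for m in act}
        for sp in problem.springs:
            if sp.muscle is not None:
                sp.scale = min(plateau.get(sp.muscle, 0.0) * scale
                               / sigma_max.get(sp.muscle, np.inf), 1.0)
        pres = _prescribed_vector(mesh, bc, imposed_nodes, scale=scale)
        try:
            u_new, norms = newton_solve(problem, u, constrained, pres,
                                        scale, options,
                                        linear_solver=linear_solver)
        except (NonConvergence, ElementInversion) as err:
            if initial_guess is not None and scale_done == 0.0:
                if not guess_fallback:
                    raise NonConvergence(
                        f"warm-started solve failed: {err}") from err
                # bad warm start: restart continuation from zero
                u = np.zeros(problem.n_dof)
                dscale = base_dscale
                initial_guess = None
                continue
            cuts += 1
            if cuts > options.max_cuts:
                raise NonConvergence(
                    f"static continuation failed at load scale {scale:.4f} "
                    f"after {cuts - 1} cuts: {err}",
                    {"scale": scale, "cause": str(err)}) from err
            if cuts % 4 == 0 and scale_done < 1.0 - 2 * base_dscale:
                # repeated cuts suggest a fold in the equilibrium path:
                # attempt to leap over it with an extra-large step
                dscale = 2.0 * base_dscale
            else:
                dscale *= 0.5
            continue
        u = u_new
        scale_done = scale
        dscale = base_dscale  # restore the nominal step after success
        if record_steps or scale_done >= 1.0 - 1e-12:
            history.append(u.copy())
            norms_all.append(norms)
            contact_all.append(getattr(problem, "contact_active", 0))
            times.append(scale_done)

    u_hist = np.array(history)
    disp_mm = u_hist.reshape(len(history), -1, 3) / MM
    landmarks = {n: np.stack([_landmark_disp(mesh, d)[n] for d in disp_mm])
                 for n in _landmark_names(mesh)}
    Jh = np.stack([_element_J(problem, uu) for uu in u_hist])
    return SimulationResult(np.array(times), disp_mm, landmarks, Jh,
                            norms_all, contact_all, converged=True,
                            diagnostics={"load_cuts": cuts})


# ------------------------------------------------------------- dynamics
@dataclass
class TransientOptions:
    scheme: str = "newmark"       # "newmark" or "backward-euler"
    beta: float = 0.25
    gamma: float = 0.5
    rayleigh_alpha: float = 20.0  # 1/s
    rayleigh_beta: float = 0.002  # s
    newton: NewtonOptions = field(default_factory=NewtonOptions)
    max_step_cuts: int = 8
    steady_ke_fraction: float = 1e-5   # KE / max(KE) threshold
    #: first-order low-pass time constant (s) for the fiber strain rate fed
    #: to the force-velocity factor; stabilizes the semi-implicit coupling
    edot_filter_tau: float = 0.15


def solve_transient(mesh: Mesh, material=None, muscles=None,
                    schedules: list[ActivationSchedule] = (),
                    bc: BoundaryConditions = None, t_end: float = 1.0,
                    dt: float = 0.01, contacts=(),
                    options: TransientOptions = None) -> SimulationResult:
    """Implicit transient analysis with piecewise-linear activation.

    Muscle force-velocity factors use the fiber strain rate of the previous
    step (semi-implicit); the Rayleigh damping matrix is alpha*M + beta*K0
    with K0 the tangent at rest.  Returns the full displacement history and
    flags the first steady-state sample (kinetic energy below
    ``steady_ke_fraction`` of its running maximum after the last schedule
    breakpoint).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bc = bc or BoundaryConditions()
    bc.validate()
    options = options or TransientOptions()
    problem, act = _build_problem(mesh, material, muscles, bc, contacts)
    constrained, imposed_nodes = build_dof_partition(
        mesh, bc.fixed_sets, list(bc.imposed))
    free = ~constrained
    sched = {s.muscle: s for s in schedules}

    Mmat = problem.mass_matrix()
    _, K0 = problem.assemble(np.zeros(problem.n_dof), external_scale=0.0)
    Cmat = options.rayleigh_alpha * Mmat + options.rayleigh_beta * K0

    if options.scheme == "newmark":
        beta, gamma = options.beta, options.gamma
    elif options.scheme == "backward-euler":
        beta, gamma = 1.0, 1.0  # placeholders; c1, c2 below coincide
    else:
        raise ValueError(f"unknown scheme {options.scheme!r}")
    backward_euler = options.scheme == "backward-euler"

    u = np.zeros(problem.n_dof)
    v = np.zeros(problem.n_dof)
    r0, _ = problem.assemble(u, external_scale=1.0, with_tangent=False)
    a = np.zeros(problem.n_dof)
    a[free] = splu(Mmat[free][:, free].tocsc()).solve(-r0[free])

    lam_prev = [m.lam_prev.copy() for m in act]
    edot_filt = [np.zeros_like(m.lam_prev) for m in act]
    last_bp = max([s.breakpoints[-1][0] for s in schedules], default=0.0)

    times = [0.0]
    disp = [np.zeros((problem.n_nodes, 3))]
    Jh = [_element_J(problem, u)]
    ke_hist = [0.0]
    norms_all, contact_all = [[]], [0]
    steady_idx = None
    ke_max = 0.0

    t = 0.0
    step_dt = dt
    cuts = 0
    consecutive_cuts = 0
    while t < t_end - 1e-12:
        h = min(step_dt, t_end - t)
        t_new = t + h
        c1 = 1.0 / (beta * h * h)
        c2 = gamma / (beta * h)
        # activation with lagged strain rate
        lam_now = problem.fiber_stretches(u)
        theta = min(1.0, h / max(options.edot_filter_tau, h))
        edot_trial = []
        for m, lp, ln, ef in zip(act, lam_prev, lam_now, edot_filt):
            s_val = sched[m.name](t_new) if m.name in sched else 0.0
            m.hill.activation = min(s_val / m.hill.sigma_max, 1.0)
            ef_new = (1.0 - theta) * ef + theta * (ln - lp) / h
            edot_trial.append(ef_new)
            m.base_stress[:] = s_val * m.hill.f_v(ef_new)
        sigma_max = {m.name: m.hill.sigma_max for m in act}
        for sp in problem.springs:
            if sp.muscle is not None:
                s_val = sched[sp.muscle](t_new) if sp.muscle in sched else 0.0
                sp.scale = min(s_val / sigma_max.get(sp.muscle, np.inf), 1.0)
        pres = np.zeros(problem.n_dof)
        for name, nids in imposed_nodes.items():
            d = bc.trajectory_at(name, t_new) * MM
            for nid in nids:
                pres[3 * nid:3 * nid + 3] = d

        def newmark_va(u_new):
            if backward_euler:
                v_new = (u_new - u) / h
                a_new = (v_new - v) / h
            else:
                a_new = c1 * (u_new - u - h * v) \
                    - (1.0 / (2 * beta) - 1.0) * a
                v_new = v + h * ((1.0 - gamma) * a + gamma * a_new)
            return v_new, a_new

        def dyn_residual(u_vec):
            r, _ = problem.assemble(u_vec, external_scale=1.0,
                                    with_tangent=False)
            v_n, a_n = newmark_va(u_vec)
            return r + Mmat @ a_n + Cmat @ v_n

        u_trial = u.copy()
        u_trial[constrained] = pres[constrained]
        ok = False
        norms = []
        lu = None
        try:
            r_dyn = dyn_residual(u_trial)
            rn = np.linalg.norm(r_dyn[free])
            ref = max(np.linalg.norm(problem.f_gravity[free]), rn,
                      options.newton.abs_tol)
            for it in range(options.newton.max_iter):
                norms.append(rn)
                if not np.isfinite(rn):
                    break
                if rn <= options.newton.tol * ref:
                    ok = True
                    break
                refresh = lu is None or (
                    len(norms) >= 2
                    and norms[-1] > options.newton.reuse_contraction * norms[-2])
                if refresh:
                    _, K = problem.assemble(u_trial, external_scale=1.0)
                    Keff = (K + c1 * Mmat + c2 * Cmat)[free][:, free].tocsc()
                    lu = splu(Keff, permc_spec="COLAMD")
                du = lu.solve(-r_dyn[free])
                step = np.abs(du).max()
                if step > options.newton.max_increment:
                    du *= options.newton.max_increment / step
                alpha, accepted = 1.0, False
                while alpha >= options.newton.min_alpha:
                    u_try = u_trial.copy()
                    u_try[free] += alpha * du
                    try:
                        r_try = dyn_residual(u_try)
                        rn_try = np.linalg.norm(r_try[free])
                    except ElementInversion:
                        alpha *= 0.5
                        continue
                    if np.isfinite(rn_try) and rn_try < rn:
                        accepted = True
                        break
                    alpha *= 0.5
                if not accepted:
                    break
                u_trial, r_dyn, rn = u_try, r_try, rn_try
                if alpha < 1.0:
                    lu = None
        except ElementInversion:
            ok = False
        if not ok:
            cuts += 1
            consecutive_cuts += 1
            if consecutive_cuts > options.max_step_cuts:
                raise NonConvergence(
                    f"transient step at t={t_new:.4f}s failed after "
                    f"{consecutive_cuts - 1} consecutive cuts",
                    {"t": t_new, "norms": norms})
            step_dt *= 0.5
            continue
        consecutive_cuts = 0

        v, a = newmark_va(u_trial)
        u = u_trial
        t = t_new
        step_dt = min(dt, 2.0 * step_dt)  # recover after successful steps
        lam_prev = lam_now
        edot_filt = edot_trial
        ke = 0.5 * float(v @ (Mmat @ v))
        ke_max = max(ke_max, ke)
        times.append(t)
        disp.append(u.reshape(-1, 3) / MM)
        Jh.append(_element_J(problem, u))
        ke_hist.append(ke)
        norms_all.append(norms)
        contact_all.append(getattr(problem, "contact_active", 0))
        if (steady_idx is None and t > last_bp and ke_max > 0
                and ke <= options.steady_ke_fraction * ke_max):
            steady_idx = len(times) - 1

    disp = np.array(disp)
    landmarks = {n: np.stack([_landmark_disp(mesh, d)[n] for d in disp])
                 for n in _landmark_names(mesh)}
    return SimulationResult(np.array(times), disp, landmarks, np.array(Jh),
                            norms_all, contact_all, converged=True,
                            steady_state_index=steady_idx,
                            kinetic_energy=np.array(ke_hist),
                            diagnostics={"step_cuts": cuts})


# ------------------------------------------------------------- presets
def apply_phoneme_preset(phoneme: str, ramp_s: float = 0.2,
                         hold_s: float = 0.8):
    """Activation schedules + jaw/hyoid boundary conditions for a preset
    phoneme in {a, u, i, t, k}.

    Hyoid displacement (X front+, Y up+) is imposed on the phantom's
    ``hyoid_attachment`` node set; the mandibular opening is mapped to a
    lowering of the ``mandible_attachment`` set.  Both ramp over ``ramp_s``
    seconds and hold.
    """
    schedules = schedule_from_table(phoneme, ramp_s=ramp_s, hold_s=hold_s)
    jh = jaw_hyoid_displacements(phoneme)
    t1 = max(ramp_s, 1e-6)
    t2 = t1 + hold_s
    hyoid = (jh["hyoid_x"], jh["hyoid_y"], 0.0)
    jaw = (0.0, -jh["jaw_opening"], 0.0)
    bc = BoundaryConditions(
        fixed_sets=("floor_fixed",),
        imposed={
            "hyoid_attachment": [(0.0, (0.0, 0.0, 0.0)), (t1, hyoid), (t2, hyoid)],
            "mandible_attachment": [(0.0, (0.0, 0.0, 0.0)), (t1, jaw), (t2, jaw)],
        },
    )
    return schedules, bc


def solve_phoneme_posture(phoneme: str, spec=None, material=None,
                          half: bool = True, load_scale_steps: int = 3,
                          options: NewtonOptions = None,
                          method: str = "auto", relax_dt: float = 0.02,
                          relax_t_end: float = 0.8,
                          transient_options: TransientOptions = None):
    """Steady-state posture for a preset phoneme on the tongue phantom.

    Computes the static limit of the held activation (the transient
    solution converges to it once kinetic energy has decayed).  ``method``:

    * ``"static"`` — incremental static continuation only;
    * ``"relax"`` — dynamic relaxation (a short damped transient through
      the activation ramp, robust through folds in the equilibrium path)
      followed by a warm-started static polish to the 1e-6 residual;
    * ``"auto"`` — static continuation first, dynamic relaxation as the
      fallback for strongly activated postures.

    With ``half`` the problem is solved on the symmetric half phantom with
    the u_z = 0 mid-sagittal condition — exact for these symmetric load
    cases and several times faster.  Returns (mesh, SimulationResult).
    """
    from .phantom import PhantomSpec, generate_tongue_phantom

    spec = spec or PhantomSpec()
    if half and not spec.symmetric_half:
        spec = replace(spec, symmetric_half=True)
    mesh = generate_tongue_phantom(spec)
    muscles = muscle_sets_from_mesh(mesh)
    schedules, bc = apply_phoneme_preset(phoneme, ramp_s=0.3,
                                         hold_s=relax_t_end - 0.3)
    if spec.symmetric_half:
        bc.fixed_sets = tuple(bc.fixed_sets) + (
            ("midsagittal", (False, False, True)),)
    from .phantom import styloglossus_cables
    bc.springs = list(bc.springs) + [
        c for c in styloglossus_cables(spec) if c[0] in mesh.node_sets]

    def relax():
        topt = transient_options or TransientOptions(
            scheme="backward-euler", steady_ke_fraction=1e-4)
        tres = solve_transient(mesh, material=material, muscles=muscles,
                               schedules=schedules, bc=bc, t_end=relax_t_end,
                               dt=relax_dt, options=topt)
        return solve_static(mesh, material=material, muscles=muscles, bc=bc,
                            schedules=schedules,
                            load_scale_steps=load_scale_steps,
                            options=options,
                            initial_guess=tres.final_displacement,
                            guess_fallback=False)

    if method == "relax":
        res = relax()
    elif method == "static":
        res = solve_static(mesh, material=material, muscles=muscles, bc=bc,
                           schedules=schedules,
                           load_scale_steps=load_scale_steps, options=options)
    elif method == "auto":
        # strongly activated postures go straight to dynamic relaxation:
        # their static continuation paths tend to fold
        if max((s.plateau for s in schedules), default=0.0) > 2e4:
            res = relax()
        else:
            try:
                res = solve_static(mesh, material=material, muscles=muscles,
                                   bc=bc, schedules=schedules,
                                   load_scale_steps=load_scale_steps,
                                   options=options)
            except NonConvergence:
                res = relax()
    else:
        raise ValueError(f"unknown method {method!r}")
    return mesh, res
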