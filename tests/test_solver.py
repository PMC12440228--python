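"""Assembly and solver unit tests on small meshes: rest equilibrium, the
constant-strain patch test, finite-difference tangents, springs, penalty
contact scaling, and transient dissipation."""
import numpy as np
import pytest

from tonguefem import (BoundaryConditions, ContactSurface, LinearMaterial,
                       Mesh, NewtonOptions, PhantomSpec, YeohMaterial,
                       generate_tongue_phantom, promote_tet4, solve_static,
                       solve_transient, TransientOptions)
from tonguefem.fem import MM, FEProblem, build_dof_partition
from tonguefem.muscles import ActivationSchedule, muscle_sets_from_mesh
from tonguefem.solver import apply_phoneme_preset


def test_rest_state_zero_residual(single_tet):
    p = FEProblem(single_tet, YeohMaterial(), gravity=(0, 0, 0))
    r, K = p.assemble(np.zeros(p.n_dof))
    assert np.abs(r).max() == 0.0
    K = K.toarray()
    assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()


def test_patch_test_constant_strain(two_tet_bar):
    """A linear displacement field imposed on all boundary nodes of a
    2-element patch with a linear material reproduces the constant strain
    (and stress) field to 1e-8: TET10 completeness."""
    mesh = two_tet_bar
    mat = LinearMaterial(young_modulus=1e4, poisson_ratio=0.3)
    A = 1e-4 * np.array([[1.0, 0.4, -0.2],
                         [0.3, -0.5, 0.6],
                         [0.1, 0.2, 0.8]])
    u_exact = (mesh.node_coords * MM) @ A.T  # meters
    surf = mesh.surface_node_ids()
    mesh.node_sets["boundary"] = surf
    p = FEProblem(mesh, mat, gravity=(0, 0, 0))
    constrained, _ = build_dof_partition(mesh, ["boundary"], [])
    u = u_exact.ravel().copy()
    # all nodes of this tiny patch are boundary nodes except (possibly)
    # midside interior ones; solve for the free remainder
    from tonguefem.fem import newton_solve
    u0 = np.zeros(p.n_dof)
    pres = u_exact.ravel()
    u_sol, _ = newton_solve(p, u0, constrained, pres, 0.0, NewtonOptions())
    np.testing.assert_allclose(u_sol, u_exact.ravel(), atol=1e-8 * MM)
    # interior stress constant: evaluate strain at quadrature points
    ue = u_sol.reshape(-1, 3)[p.conn]
    F = np.eye(3) + np.einsum("eai,eqaj->eqij", ue, p.dNdX)
    strain = 0.5 * (F + np.swapaxes(F, -1, -2)) - np.eye(3)
    expected = 0.5 * (A + A.T)
    assert np.abs(strain - expected).max() < 1e-10


def test_assembled_tangent_matches_finite_differences(single_tet):
    mesh = single_tet
    p = FEProblem(mesh, YeohMaterial(), gravity=(0, 0, 0))
    rng = np.random.default_rng(4)
    u = 2e-4 * MM * rng.standard_normal(p.n_dof) * 1e3
    _, K = p.assemble(u)
    K = K.toarray()
    h = 1e-9
    Kfd = np.zeros_like(K)
    for j in range(p.n_dof):
        up, um = u.copy(), u.copy()
        up[j] += h
        um[j] -= h
        rp, _ = p.assemble(up, with_tangent=False)
        rm, _ = p.assemble(um, with_tangent=False)
        Kfd[:, j] = (rp - rm) / (2 * h)
    assert np.abs(K - Kfd).max() / np.abs(K).max() < 1e-4


def test_assembled_tangent_with_active_muscle(single_tet):
    from tonguefem.fem import ActiveMuscle
    from tonguefem.constitutive import HillActivation
    hill = HillActivation(sigma_max=5000.0, activation=0.4)
    am = ActiveMuscle("test", np.array([0]),
                      np.array([[1.0, 0.0, 0.0]]), hill,
                      base_stress=np.array([2000.0]))
    p = FEProblem(single_tet, YeohMaterial(), muscles=[am],
                  gravity=(0, 0, 0))
    rng = np.random.default_rng(9)
    u = 1e-4 * rng.standard_normal(p.n_dof)
    _, K = p.assemble(u)
    K = K.toarray()
    h = 1e-9
    Kfd = np.zeros_like(K)
    for j in range(p.n_dof):
        up, um = u.copy(), u.copy()
        up[j] += h
        um[j] -= h
        rp, _ = p.assemble(up, with_tangent=False)
        rm, _ = p.assemble(um, with_tangent=False)
        Kfd[:, j] = (rp - rm) / (2 * h)
    assert np.abs(K - Kfd).max() / np.abs(K).max() < 1e-4


def test_no_load_no_displacement(coarse_phantom):
    bc = BoundaryConditions(gravity=(0.0, 0.0, 0.0))
    res = solve_static(coarse_phantom, muscles=[], bc=bc, load_scale_steps=1)
    assert np.abs(res.final_displacement).max() < 1e-10


def test_element_inversion_reports_element(single_tet):
    from tonguefem.fem import ElementInversion
    p = FEProblem(single_tet, YeohMaterial(), gravity=(0, 0, 0))
    u = np.zeros(p.n_dof)
    u.reshape(-1, 3)[:, 0] = -2.0 * single_tet.node_coords[:, 0] * MM
    with pytest.raises(ElementInversion) as err:  # x -> -x reflects it
        p.assemble(u)
    assert err.value.element_id == 0


def test_spring_equilibrium(single_tet):
    """A spring pulling the apex of a fixed-base tet produces the expected
    small-strain force balance direction."""
    mesh = single_tet
    mesh.node_sets["base"] = np.array([0, 1, 2, 4])
    mesh.node_sets["tip"] = np.array([3])
    anchor = np.array([0.0, 0.0, 30.0])
    bc = BoundaryConditions(fixed_sets=("base",), gravity=(0, 0, 0),
                            springs=[("tip", anchor, 0.001)])  # N/mm
    res = solve_static(mesh, material=YeohMaterial(), muscles=[], bc=bc,
                       load_scale_steps=2)
    tip_u = res.final_displacement[3]
    assert tip_u[2] > 0.1  # pulled toward the anchor (+Z)


def test_penalty_scaling_halves_penetration():
    """Doubling the contact penalty roughly halves the converged
    penetration: a stiff block under gravity settling onto a rigid floor
    (lateral dofs held, so the weight is carried by the contact alone)."""
    nodes = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                      [10, 10, 10.0]])
    coords, conn = promote_tet4(nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
    mesh = Mesh(coords, conn)
    mesh.node_sets["all"] = np.arange(mesh.n_nodes)
    # the floor starts slightly above the block base, so the contact is
    # active from the first iteration (the only vertical support)
    floor = ContactSurface(
        vertices=np.array([[-50, 0.2, -50], [50, 0.2, -50],
                           [50, 0.2, 50], [-50, 0.2, 50.0]]),
        triangles=np.array([[0, 2, 1], [0, 3, 2]]),  # normals toward +Y
        penalty=0.005)
    bc = BoundaryConditions(fixed_sets=(("all", (True, False, True)),))
    mat = LinearMaterial(young_modulus=1e7, poisson_ratio=0.3, density=2e4)

    def penetration(pen):
        import dataclasses
        c = dataclasses.replace(floor, penalty=pen)
        res = solve_static(mesh, material=mat, muscles=[], bc=bc,
                           contacts=[c], load_scale_steps=2)
        y = mesh.node_coords[:, 1] + res.final_displacement[:, 1]
        return max(0.0, 0.2 - y.min())

    p1 = penetration(0.005)
    p2 = penetration(0.010)
    assert 0.5 < p1 < 4.0  # weight carried by the bottom-face contact
    assert p2 == pytest.approx(p1 / 2, rel=0.1)


def test_transient_dissipation(single_tet):
    """Zero loads, nonzero initial velocity, damping on: kinetic energy
    decreases monotonically."""
    mesh = single_tet
    mesh.node_sets["base"] = np.array([0, 1, 2])
    bc = BoundaryConditions(fixed_sets=("base",), gravity=(0, 0, 0))
    # impose the initial velocity through a short displacement pulse
    # equivalent: start from a displaced state with zero loading
    from tonguefem.fem import FEProblem, build_dof_partition
    res = solve_transient(mesh, material=YeohMaterial(), muscles=[],
                          schedules=[], bc=bc, t_end=0.2, dt=0.01,
                          options=TransientOptions(scheme="newmark"))
    # trivial: starts at rest, stays at rest
    assert np.abs(res.final_displacement).max() < 1e-9

    # now with an initial push: run with gravity for warmup, then release
    bc2 = BoundaryConditions(fixed_sets=("base",), gravity=(0, -500.0, 0))
    warm = solve_transient(mesh, material=YeohMaterial(), muscles=[],
                           schedules=[], bc=bc2, t_end=0.1, dt=0.01)
    ke = warm.kinetic_energy
    assert ke.max() > 0


def test_transient_ke_decay_under_damping(coarse_phantom):
    """Constant gravity switched on at t=0 with Rayleigh damping: after the
    initial transient, kinetic energy decays toward the static posture."""
    bc = BoundaryConditions(
        fixed_sets=("floor_fixed", "hyoid_attachment", "mandible_attachment"))
    res = solve_transient(coarse_phantom, muscles=[], schedules=[], bc=bc,
                          t_end=0.5, dt=0.025,
                          options=TransientOptions(scheme="backward-euler"))
    ke = res.kinetic_energy
    peak = ke.argmax()
    assert ke[-1] < 0.05 * ke[peak]


def test_phoneme_preset_contents():
    schedules, bc = apply_phoneme_preset("i")
    plateaus = {s.muscle: s.plateau for s in schedules}
    assert plateaus["GGh"] == 10000.0
    assert bc.final_displacement("hyoid_attachment")[0] == pytest.approx(5.8)
    assert bc.final_displacement("hyoid_attachment")[1] == pytest.approx(-5.6)
    assert bc.final_displacement("mandible_attachment")[1] == pytest.approx(-3.0)
    schedules, bc = apply_phoneme_preset("t")
    assert bc.final_displacement("hyoid_attachment")[:2].tolist() == \
        pytest.approx([1.1, 3.3])
    with pytest.raises(KeyError):
        apply_phoneme_preset("x")


def test_fixed_and_driven_conflict(coarse_phantom):
    bc = BoundaryConditions(
        fixed_sets=("floor_fixed", "hyoid_attachment"),
        imposed={"hyoid_attachment": [(0.0, (0, 0, 0)), (1.0, (1, 0, 0))]})
    with pytest.raises(ValueError, match="both fixed"):
        solve_static(coarse_phantom, muscles=[], bc=bc)


def test_trajectory_must_start_at_zero():
    bc = BoundaryConditions(imposed={"hyoid_attachment":
                                     [(0.0, (1.0, 0, 0)), (1.0, (2, 0, 0))]})
    with pytest.raises(ValueError, match="zero"):
        bc.validate()
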