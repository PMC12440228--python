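"""Constitutive oracles: Yeoh energy/stress closed forms, finite-difference
consistency, objectivity and isotropy, and the Hill active element."""
import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from tonguefem import (HillActivation, YeohMaterial, LinearMaterial,
                       active_stress, bulk_modulus, two_fiber_active_stress,
                       yeoh_energy, yeoh_stress_and_tangent)
from tonguefem.constitutive import pk2_and_tangent, yeoh_pk2_and_tangent

C10, C20, NU = 192.0, 90.0, 0.49


@pytest.fixture(scope="module")
def tongue():
    return YeohMaterial()


# ------------------------------------------------------------ bulk modulus
def test_bulk_modulus_formula():
    # direct evaluation of the penalty bulk relation at the tongue values
    assert bulk_modulus(192.0, 0.49) == 2.0 * 192.0 / (1.0 - 2 * 0.49)
    assert bulk_modulus(192.0, 0.49) == pytest.approx(19200.0, rel=1e-12)
    c10 = 77.0
    assert bulk_modulus(c10, 0.0) == 2.0 * c10


def test_bulk_modulus_monotone_and_errors():
    ks = [bulk_modulus(C10, nu) for nu in (0.0, 0.2, 0.4, 0.45, 0.49, 0.499)]
    assert all(k2 > k1 for k1, k2 in zip(ks, ks[1:]))
    with pytest.raises(ValueError):
        bulk_modulus(C10, 0.5)


def test_material_invariants(tongue):
    assert tongue.bulk_modulus == 2 * tongue.c10 / (1 - 2 * tongue.poisson_ratio)
    with pytest.raises(ValueError):
        YeohMaterial(c10=-1.0)
    with pytest.raises(ValueError):
        YeohMaterial(poisson_ratio=0.5)
    with pytest.raises(ValueError):
        LinearMaterial(young_modulus=0.0, poisson_ratio=0.3)


# ------------------------------------------------------------------ energy
def test_energy_zero_at_identity_and_rotation(tongue):
    assert yeoh_energy(np.eye(3), tongue) == 0.0
    Q = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
    assert yeoh_energy(Q, tongue) == pytest.approx(0.0, abs=1e-10)


def test_energy_isochoric_uniaxial_closed_form(tongue):
    lam = 1.2
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    ib1 = lam ** 2 + 2.0 / lam
    expected = C10 * (ib1 - 3) + C20 * (ib1 - 3) ** 2
    assert yeoh_energy(F, tongue) == pytest.approx(expected, rel=1e-12)
    # cross-check through the generic J^(-2/3) pathway with a volumetric part
    F2 = 1.01 * F
    J = np.linalg.det(F2)
    ib1b = J ** (-2 / 3) * np.trace(F2.T @ F2)
    expected2 = (C10 * (ib1b - 3) + C20 * (ib1b - 3) ** 2
                 + 0.5 * tongue.bulk_modulus * (J - 1) ** 2)
    assert yeoh_energy(F2, tongue) == pytest.approx(expected2, rel=1e-12)


def test_energy_nonnegative_random(tongue):
    rng = np.random.default_rng(7)
    for _ in range(50):
        F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.05:
            continue
        assert yeoh_energy(F, tongue) >= -1e-12
    with pytest.raises(ValueError):
        yeoh_energy(np.diag([1.0, 1.0, -1.0]), tongue)


# ------------------------------------------------------------------ stress
def test_stress_zero_at_identity(tongue):
    sigma, _ = yeoh_stress_and_tangent(np.eye(3), tongue)
    assert np.abs(sigma).max() < 1e-12


def test_incompressible_uniaxial_oracle(tongue):
    """sigma_axial - sigma_lateral = 2(lam^2 - 1/lam)(C10 + 2 C20 (Ib1-3));
    the nu=0.49 penalty solution must match the incompressible closed form
    within 5%."""
    for lam in (0.8, 0.9, 1.1, 1.2, 1.3):
        ib1 = lam ** 2 + 2.0 / lam
        oracle = 2 * (lam ** 2 - 1 / lam) * (C10 + 2 * C20 * (ib1 - 3))

        def lateral_stress(mu):
            s, _ = yeoh_stress_and_tangent(np.diag([lam, mu, mu]), tongue)
            return s[1, 1]

        mu = brentq(lateral_stress, 0.4, 1.8, xtol=1e-13)
        s, _ = yeoh_stress_and_tangent(np.diag([lam, mu, mu]), tongue)
        assert s[0, 0] - s[1, 1] == pytest.approx(oracle, rel=0.05)
    # the paper-parameter spot value at lam = 1.2
    lam = 1.2
    ib1 = lam ** 2 + 2 / lam
    assert 2 * (lam ** 2 - 1 / lam) * (C10 + 2 * C20 * (ib1 - 3)) == \
        pytest.approx(256.256, abs=1e-3)


def test_stress_finite_difference_consistency(tongue):
    """Cauchy stress consistent with the energy via dW/dF to 1e-5 relative."""
    rng = np.random.default_rng(3)
    checked = 0
    while checked < 20:
        F = np.eye(3) + 0.25 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.3:
            continue
        sigma, _ = yeoh_stress_and_tangent(F, tongue)
        P = np.zeros((3, 3))
        h = 1e-6
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                P[i, j] = (yeoh_energy(Fp, tongue)
                           - yeoh_energy(Fm, tongue)) / (2 * h)
        sigma_fd = P @ F.T / np.linalg.det(F)
        scale = max(np.abs(sigma).max(), 1.0)
        assert np.abs(sigma - sigma_fd).max() / scale < 1e-5
        checked += 1


def test_tangent_finite_difference_and_symmetry(tongue):
    """Material tangent dS/dE matches central differences of the PK2 stress
    at 1e-5 relative and has major symmetry."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.4:
            continue
        C = F.T @ F
        S, CC = yeoh_pk2_and_tangent(C, tongue)
        assert np.abs(CC - np.einsum("klij->ijkl", CC)).max() \
            < 1e-8 * np.abs(CC).max()
        h = 1e-7
        for (k, l) in ((0, 0), (1, 1), (0, 1), (1, 2)):
            dC = np.zeros((3, 3))
            dC[k, l] = dC[l, k] = h
            Sp, _ = yeoh_pk2_and_tangent(C + dC, tongue)
            Sm, _ = yeoh_pk2_and_tangent(C - dC, tongue)
            fd = (Sp - Sm) / (2 * h)
            # dE = dC/2; with minor symmetry the column reads off directly
            an = CC[:, :, k, l] if k != l else CC[:, :, k, k] / 2.0
            assert np.abs(an - fd).max() / max(np.abs(CC).max(), 1.0) < 1e-5


def test_objectivity(tongue):
    """W(QF) = W(F) and sigma(QF) = Q sigma(F) Q^T for rotations Q."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.4:
            continue
        Q = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
        assert yeoh_energy(Q @ F, tongue) == pytest.approx(
            yeoh_energy(F, tongue), rel=1e-10, abs=1e-10)
        s1, _ = yeoh_stress_and_tangent(F, tongue)
        s2, _ = yeoh_stress_and_tangent(Q @ F, tongue)
        assert np.allclose(s2, Q @ s1 @ Q.T, atol=1e-10 * max(np.abs(s1).max(), 1))


def test_passive_isotropy_permutation(tongue):
    """Permuting principal stretches permutes principal Cauchy stresses."""
    lams = np.array([1.15, 0.95, 0.8])
    s1, _ = yeoh_stress_and_tangent(np.diag(lams), tongue)
    s2, _ = yeoh_stress_and_tangent(np.diag(lams[[2, 0, 1]]), tongue)
    assert np.allclose(np.diag(s1)[[2, 0, 1]], np.diag(s2), rtol=1e-12)


def test_uniaxial_monotonicity(tongue):
    """Drucker-like stability: uniaxial stress monotone in stretch on
    lam in [0.7, 1.4] (volume-preserving uniaxial states)."""
    lams = np.linspace(0.7, 1.4, 36)
    stresses = []
    for lam in lams:
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        s, _ = yeoh_stress_and_tangent(F, tongue)
        stresses.append(s[0, 0] - s[1, 1])
    assert np.all(np.diff(stresses) > 0)


# -------------------------------------------------------------------- Hill
def test_hill_curve_invariants():
    h = HillActivation(sigma_max=1000.0)
    assert h.f_l(h.lambda_opt) == 1.0
    assert h.f_v(0.0) == 1.0
    assert h.f_v(-h.edot_max) == 0.0
    assert h.f_v(-2 * h.edot_max) == 0.0
    assert h.f_v(10 * h.edot_max) == h.lengthening_cap
    with pytest.raises(ValueError):
        HillActivation(sigma_max=1.0, activation=1.2)


def test_active_stress_examples():
    h = HillActivation(sigma_max=5000.0, activation=0.0)
    m = np.array([1.0, 0.0, 0.0])
    assert np.abs(active_stress(h, 1.0, 0.0, m)).max() == 0.0
    h.activation = 1.0
    s = active_stress(h, h.lambda_opt, 0.0, m)
    assert s[0, 0] == pytest.approx(5000.0)        # isometric optimum
    assert np.abs(s - np.outer(m, m) * 5000).max() < 1e-9
    assert np.abs(active_stress(h, 1.0, -h.edot_max, m)).max() == 0.0
    with pytest.raises(ValueError):
        active_stress(h, 1.0, 0.0, np.array([1.0, 1.0, 0.0]))
    with pytest.raises(ValueError):
        active_stress(h, -0.1, 0.0, m)


def test_two_fiber_superposition():
    h1 = HillActivation(sigma_max=3000.0, activation=0.5)
    h2 = HillActivation(sigma_max=8000.0, activation=0.25)
    m1 = np.array([1.0, 0.0, 0.0])
    m2 = np.array([0.0, 1.0, 0.0])
    # second activation zero -> equals the single-fiber result exactly
    h2_off = HillActivation(sigma_max=8000.0, activation=0.0)
    s = two_fiber_active_stress(h1, h2_off, m1, m2)
    np.testing.assert_array_equal(s, active_stress(h1, 1.0, 0.0, m1))
    # orthogonal fibers, equal states, F = I -> equal eigenvalues
    h2_eq = HillActivation(sigma_max=3000.0, activation=0.5)
    s = two_fiber_active_stress(h1, h2_eq, m1, m2)
    assert s[0, 0] == pytest.approx(s[1, 1])
    # order swap -> identical stress
    s_ab = two_fiber_active_stress(h1, h2, m1, m2)
    s_ba = two_fiber_active_stress(h2, h1, m2, m1)
    np.testing.assert_allclose(s_ab, s_ba, rtol=1e-15)


def test_two_fiber_uses_deformation_gradient():
    h = HillActivation(sigma_max=1000.0, activation=1.0)
    m1 = np.array([1.0, 0.0, 0.0])
    m2 = np.array([0.0, 0.0, 1.0])
    F = np.diag([0.8, 1.0, 1.1])
    s = two_fiber_active_stress(h, h, m1, m2, F=F)
    # f_l penalizes the shortened fiber 1 more than the lengthened fiber 2
    assert s[0, 0] < s[2, 2]
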