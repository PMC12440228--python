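"""Constitutive models: passive Yeoh hyperelasticity, linear (Saint
Venant-Kirchhoff) elasticity, and Hill-type active muscle stress.

The passive tongue tissue follows a two-term Yeoh law with a quadratic
volumetric penalty,

    W = C10 (Ib1 - 3) + C20 (Ib1 - 3)^2 + K/2 (J - 1)^2,

where Ib1 = J^(-2/3) tr(C) is the first deviatoric invariant of the right
Cauchy-Green tensor C = F^T F, J = det F, and the bulk modulus derives from
C10 and the Poisson ratio as K = 2 C10 / (1 - 2 nu).  The passive response
is isotropic: muscle anisotropy enters only through the active stress.

A recruited muscle adds a uniaxial Cauchy stress sigma_max * a * f_l * f_v
along the (deformed) fiber direction — tension-positive, so that a positive
activation contracts the fiber.  The force-length factor f_l is a Gaussian
bell centred on the optimal fiber stretch; the force-velocity factor f_v is
the classic Hill hyperbola for shortening with a mild linear enhancement
(capped) for lengthening.  Elements in which two muscles interdigitate
superimpose two such uniaxial contributions.

Batched functions accept arrays of shape (..., 3, 3) and are used directly
by the assembly loop; the scalar-state wrappers (`yeoh_energy`,
`yeoh_stress_and_tangent`, `active_stress`) are the documented single-point
API.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EYE = np.eye(3)


def bulk_modulus(c10: float, poisson_ratio: float) -> float:
    """Bulk modulus K = 2 C10 / (1 - 2 nu), Pa."""
    if poisson_ratio >= 0.5:
        raise ValueError("Poisson ratio must be < 0.5")
    return 2.0 * c10 / (1.0 - 2.0 * poisson_ratio)


@dataclass(frozen=True)
class YeohMaterial:
    """Two-term Yeoh solid. Defaults are the tongue-tissue parameters
    (C10 = 192 Pa, C20 = 90 Pa, nu = 0.49, rho = 1040 kg/m^3)."""
    c10: float = 192.0            # Pa
    c20: float = 90.0             # Pa
    poisson_ratio: float = 0.49
    density: float = 1040.0       # kg/m^3

    def __post_init__(self):
        if self.c10 <= 0:
            raise ValueError("C10 must be positive")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must be in (0, 0.5)")

    @property
    def bulk_modulus(self) -> float:
        return bulk_modulus(self.c10, self.poisson_ratio)


@dataclass(frozen=True)
class LinearMaterial:
    """Saint Venant-Kirchhoff solid (linear elastic at small strain)."""
    young_modulus: float          # Pa
    poisson_ratio: float
    density: float = 1040.0       # kg/m^3

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise ValueError("Young modulus must be positive")
        if self.poisson_ratio >= 0.5:
            raise ValueError("Poisson ratio must be < 0.5")

    @property
    def lame(self) -> tuple[float, float]:
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu


# --------------------------------------------------------------- Yeoh, PK2
def _inv_sym(C: np.ndarray) -> np.ndarray:
    return np.linalg.inv(C)


def _sym4_outer(Ci: np.ndarray) -> np.ndarray:
    """(Cinv (x)s Cinv)_ijkl = 1/2 (Ci_ik Ci_jl + Ci_il Ci_jk)."""
    return 0.5 * (np.einsum("...ik,...jl->...ijkl", Ci, Ci)
                  + np.einsum("...il,...jk->...ijkl", Ci, Ci))


def yeoh_pk2_and_tangent(C: np.ndarray, mat: YeohMaterial):
    """Second Piola-Kirchhoff stress and material tangent dS/dE for the Yeoh
    law, batched over leading axes of C (..., 3, 3)."""
    c10, c20, K = mat.c10, mat.c20, mat.bulk_modulus
    I1 = np.trace(C, axis1=-2, axis2=-1)
    detC = np.linalg.det(C)
    if np.any(detC <= 0.0):
        raise ValueError("non-positive det(C): element inversion")
    J = np.sqrt(detC)
    Jm23 = J ** (-2.0 / 3.0)
    Ib1 = Jm23 * I1
    Ci = _inv_sym(C)
    A = Jm23[..., None, None] * (_EYE - (I1 / 3.0)[..., None, None] * Ci)
    psi1 = c10 + 2.0 * c20 * (Ib1 - 3.0)

    S = 2.0 * psi1[..., None, None] * A \
        + (K * (J - 1.0) * J)[..., None, None] * Ci

    a_s = (Jm23 * I1 / 3.0)
    CiCi = _sym4_outer(Ci)
    dAdC = (-(Jm23 / 3.0)[..., None, None, None, None]
            * np.einsum("ij,...kl->...ijkl", _EYE, Ci)
            - (1.0 / 3.0) * np.einsum("...ij,...kl->...ijkl", Ci, A)
            + a_s[..., None, None, None, None] * CiCi)
    CC = (8.0 * c20 * np.einsum("...ij,...kl->...ijkl", A, A)
          + 4.0 * psi1[..., None, None, None, None] * dAdC
          + (K * (2.0 * J - 1.0) * J)[..., None, None, None, None]
          * np.einsum("...ij,...kl->...ijkl", Ci, Ci)
          - (2.0 * K * (J - 1.0) * J)[..., None, None, None, None] * CiCi)
    return S, CC


def svk_pk2_and_tangent(C: np.ndarray, mat: LinearMaterial):
    """Saint Venant-Kirchhoff PK2 stress and (constant) tangent, batched."""
    lam, mu = mat.lame
    E = 0.5 * (C - _EYE)
    trE = np.trace(E, axis1=-2, axis2=-1)
    S = lam * trE[..., None, None] * _EYE + 2.0 * mu * E
    II = 0.5 * (np.einsum("ik,jl->ijkl", _EYE, _EYE)
                + np.einsum("il,jk->ijkl", _EYE, _EYE))
    CC = lam * np.einsum("ij,kl->ijkl", _EYE, _EYE) + 2.0 * mu * II
    CC = np.broadcast_to(CC, C.shape[:-2] + (3, 3, 3, 3))
    return S, CC


def pk2_and_tangent(C: np.ndarray, mat):
    if isinstance(mat, YeohMaterial):
        return yeoh_pk2_and_tangent(C, mat)
    if isinstance(mat, LinearMaterial):
        return svk_pk2_and_tangent(C, mat)
    raise TypeError(f"unknown material {type(mat).__name__}")


# -------------------------------------------------------------- scalar API
def yeoh_energy(F: np.ndarray, mat: YeohMaterial) -> float:
    """Strain energy density W(F), Pa. Zero iff F is a rotation."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise ValueError("det F must be positive")
    I1 = np.einsum("...ij,...ij->...", F, F)
    Ib1 = J ** (-2.0 / 3.0) * I1
    W = (mat.c10 * (Ib1 - 3.0) + mat.c20 * (Ib1 - 3.0) ** 2
         + 0.5 * mat.bulk_modulus * (J - 1.0) ** 2)
    return float(W) if W.ndim == 0 else W


def yeoh_stress_and_tangent(F: np.ndarray, mat: YeohMaterial):
    """Cauchy stress (3, 3, Pa) and spatial material tangent (3, 3, 3, 3).

    The tangent is the push-forward of dS/dE and possesses major symmetry;
    consistency with `yeoh_energy` is established by finite differences in
    the test suite.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise ValueError("det F must be positive")
    C = np.einsum("...ki,...kj->...ij", F, F)
    S, CC = yeoh_pk2_and_tangent(C, mat)
    sigma = np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]
    c_spat = np.einsum("...iI,...jJ,...kK,...lL,...IJKL->...ijkl",
                       F, F, F, F, CC) / J[..., None, None, None, None]
    return sigma, c_spat


# ------------------------------------------------------------- Hill active
@dataclass
class HillActivation:
    """Hill-type active element state for one muscle.

    ``activation`` is a(t) in [0, 1]; an activation schedule prescribing a
    fiber stress s(t) in Pa maps to a(t) = s(t) / sigma_max.  The
    force-length curve f_l is exp(-((lam - lambda_opt)/width)^2); the
    force-velocity curve is the Hill hyperbola for shortening,
    f_v = (1 + edot/edot_max) / (1 - edot/(k_v * edot_max)) for
    -edot_max <= edot <= 0 (zero below), and a linear enhancement
    1 + 0.4 * edot/edot_max capped at ``lengthening_cap`` for edot > 0.
    """
    sigma_max: float              # Pa
    activation: float = 0.0
    lambda_opt: float = 1.0
    width: float = 0.35
    edot_max: float = 5.0         # 1/s, max shortening strain rate
    k_v: float = 0.25             # Hill curvature
    lengthening_cap: float = 1.4

    def __post_init__(self):
        self.check_activation()

    def check_activation(self):
        if not (0.0 <= self.activation <= 1.0):
            raise ValueError(f"activation {self.activation} outside [0, 1]")

    def f_l(self, lam):
        """Force-length factor; f_l(lambda_opt) = 1."""
        lam = np.asarray(lam, dtype=float)
        out = np.exp(-(((lam - self.lambda_opt) / self.width) ** 2))
        return float(out) if out.ndim == 0 else out

    def df_l(self, lam):
        lam = np.asarray(lam, dtype=float)
        out = -2.0 * (lam - self.lambda_opt) / self.width ** 2 * self.f_l(lam)
        return float(out) if np.ndim(out) == 0 else out

    def f_v(self, edot):
        """Force-velocity factor; f_v(0) = 1, f_v(-edot_max) = 0."""
        edot = np.asarray(edot, dtype=float)
        r = edot / self.edot_max
        shortening = np.clip((1.0 + r) / (1.0 - r / self.k_v), 0.0, None)
        lengthening = np.minimum(1.0 + 0.4 * r, self.lengthening_cap)
        out = np.where(edot <= 0.0, np.where(r <= -1.0, 0.0, shortening),
                       lengthening)
        return float(out) if out.ndim == 0 else out

    def fiber_stress(self, lam, edot=0.0) -> float:
        """Active fiber Cauchy stress magnitude sigma_max*a*f_l*f_v, Pa."""
        self.check_activation()
        return self.sigma_max * self.activation * self.f_l(lam) * self.f_v(edot)


def active_stress(state: HillActivation, fiber_stretch: float,
                  fiber_strain_rate: float, m: np.ndarray) -> np.ndarray:
    """Active Cauchy stress contribution s * (m (x) m), Pa.

    ``m`` is the current (deformed) unit fiber direction; tension-positive,
    so positive activation contracts the fiber once equilibrated.
    """
    m = np.asarray(m, dtype=float)
    if abs(np.linalg.norm(m) - 1.0) > 1e-8:
        raise ValueError("fiber direction must be a unit vector")
    if fiber_stretch <= 0:
        raise ValueError("fiber stretch must be positive")
    s = state.fiber_stress(fiber_stretch, fiber_strain_rate)
    return s * np.outer(m, m)


def two_fiber_active_stress(state1: HillActivation, state2: HillActivation,
                            m1: np.ndarray, m2: np.ndarray,
                            F: np.ndarray = None,
                            strain_rates: tuple = (0.0, 0.0)) -> np.ndarray:
    """Superposed active Cauchy stress of two interwoven muscles.

    ``m1``/``m2`` are reference unit fiber directions; if ``F`` is given the
    stretches and deformed directions are computed from it, else F = I.
    """
    F = _EYE if F is None else np.asarray(F, dtype=float)
    total = np.zeros((3, 3))
    for state, m0, edot in ((state1, m1, strain_rates[0]),
                            (state2, m2, strain_rates[1])):
        m0 = np.asarray(m0, dtype=float)
        fm = F @ m0
        lam = np.linalg.norm(fm)
        total += active_stress(state, lam, edot, fm / lam)
    return total


def active_pk2_and_tangent(C: np.ndarray, m0: np.ndarray, base_stress,
                           dbase_dlam=None, state: HillActivation = None):
    """Batched active PK2 stress and tangent for the assembly loop.

    ``base_stress`` is sigma_max * a * f_v (the stretch-independent part,
    Pa) per element; the force-length factor is evaluated here from
    lam = sqrt(m0 . C m0).  S_act = J s(lam) lam^-2 (m0 (x) m0), with
    s(lam) = base_stress * f_l(lam).
    """
    state = state or HillActivation(sigma_max=1.0, activation=0.0)
    b = np.asarray(base_stress, dtype=float)
    lam2 = np.einsum("...i,...ij,...j->...", m0, C, m0)
    lam = np.sqrt(lam2)
    fl = np.exp(-(((lam - state.lambda_opt) / state.width) ** 2))
    dfl = -2.0 * (lam - state.lambda_opt) / state.width ** 2 * fl
    s = b * fl
    dsdlam = b * dfl
    J = np.sqrt(np.linalg.det(C))
    Ci = np.linalg.inv(C)
    M = np.einsum("...i,...j->...ij", m0, m0)
    S = (J * s / lam2)[..., None, None] * M
    coefA = 0.5 * J * s / lam2
    coefB = J * (dsdlam / lam2 - 2.0 * s / (lam2 * lam)) / (2.0 * lam)
    dSdC = (np.einsum("...ij,...kl->...ijkl", M, coefA[..., None, None] * Ci)
            + np.einsum("...ij,...kl->...ijkl", M, coefB[..., None, None] * M))
    return S, 2.0 * dSdC
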