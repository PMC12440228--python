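"""Yeoh passive tissue and the Hill-type active element, point-wise.

Evaluates the tongue-tissue Yeoh law (C10 = 192 Pa, C20 = 90 Pa, nu = 0.49,
bulk modulus K = 2 C10 / (1 - 2 nu) = 19200 Pa) under uniaxial stretch and
compares the penalty (nu = 0.49) stress difference with the incompressible
closed form; then shows the Hill active stress surface over stretch and
strain rate.
"""
import numpy as np
from scipy.optimize import brentq

from tonguefem import HillActivation, YeohMaterial, active_stress, \
    yeoh_energy, yeoh_stress_and_tangent

mat = YeohMaterial()
print(f"Yeoh tongue tissue: C10={mat.c10} Pa, C20={mat.c20} Pa, "
      f"nu={mat.poisson_ratio}, K={mat.bulk_modulus:.0f} Pa")

print("\nuniaxial stretch   penalty sigma_diff   incompressible oracle  (Pa)")
for lam in (0.8, 0.9, 1.1, 1.2, 1.3):
    ib1 = lam ** 2 + 2 / lam
    oracle = 2 * (lam ** 2 - 1 / lam) * (mat.c10 + 2 * mat.c20 * (ib1 - 3))

    def lateral(mu):
        s, _ = yeoh_stress_and_tangent(np.diag([lam, mu, mu]), mat)
        return s[1, 1]

    mu = brentq(lateral, 0.4, 1.8)
    s, _ = yeoh_stress_and_tangent(np.diag([lam, mu, mu]), mat)
    diff = s[0, 0] - s[1, 1]
    print(f"  lam={lam:4.2f}        {diff:10.2f}           {oracle:10.2f}"
          f"      ({100 * abs(diff - oracle) / abs(oracle):.1f}% apart)")

print("\nHill active element (sigma_max = 10 kPa, full activation):")
hill = HillActivation(sigma_max=10e3, activation=1.0)
m = np.array([1.0, 0.0, 0.0])
for lam in (0.7, 0.85, 1.0, 1.15):
    for edot in (-5.0, 0.0, 2.0):
        s = active_stress(hill, lam, edot, m)[0, 0]
        print(f"  lam={lam:4.2f} edot={edot:+4.1f}/s -> fiber stress "
              f"{s / 1e3:6.2f} kPa")
print("(the bell-shaped force-length factor peaks at the optimal stretch;")
print(" shortening at the maximum rate produces zero active stress)")
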