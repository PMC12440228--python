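"""Reference 10-node quadratic tetrahedron (TET10).

Node ordering follows the VTK quadratic-tetra convention: vertices 0-3,
then edge midpoints on edges (0,1), (1,2), (0,2), (0,3), (1,4? no: 1,3), (2,3).
All quantities are expressed in reference coordinates (xi, eta, zeta) on the
unit tetrahedron {xi, eta, zeta >= 0, xi + eta + zeta <= 1}.
"""
from __future__ import annotations

import numpy as np

# Edge -> vertex pairs, VTK ordering.  Midside node 4+k sits on EDGES[k].
EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))

N_NODES = 10


def shape_functions(points: np.ndarray) -> np.ndarray:
    """Evaluate the 10 shape functions at reference points (Q, 3) -> (Q, 10)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    lam = np.stack([1.0 - xi - eta - zeta, xi, eta, zeta], axis=1)  # (Q, 4)
    N = np.empty((pts.shape[0], N_NODES))
    for a in range(4):
        N[:, a] = lam[:, a] * (2.0 * lam[:, a] - 1.0)
    for k, (i, j) in enumerate(EDGES):
        N[:, 4 + k] = 4.0 * lam[:, i] * lam[:, j]
    return N


# dlam/d(xi,eta,zeta): rows = barycentric index
_DLAM = np.array(
    [[-1.0, -1.0, -1.0],
     [1.0, 0.0, 0.0],
     [0.0, 1.0, 0.0],
     [0.0, 0.0, 1.0]]
)


def shape_gradients(points: np.ndarray) -> np.ndarray:
    """Gradients of shape functions wrt reference coords, (Q, 10, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    lam = np.stack([1.0 - xi - eta - zeta, xi, eta, zeta], axis=1)
    Q = pts.shape[0]
    dN = np.empty((Q, N_NODES, 3))
    for a in range(4):
        dN[:, a, :] = (4.0 * lam[:, a, None] - 1.0) * _DLAM[a]
    for k, (i, j) in enumerate(EDGES):
        dN[:, 4 + k, :] = 4.0 * (lam[:, i, None] * _DLAM[j] + lam[:, j, None] * _DLAM[i])
    return dN


def quadrature(order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature rule on the reference tet. Weights sum to 1/6 (its volume).

    order=2 gives the classic symmetric 4-point rule (enough for the TET10
    stiffness of affine elements); higher orders use a collapsed (Duffy)
    Gauss-Legendre product rule which is exact to arbitrary degree.
    """
    if order <= 2:
        a = 0.5854101966249685
        b = 0.1381966011250105
        pts = np.array(
            [[b, b, b], [a, b, b], [b, a, b], [b, b, a]]
        )
        w = np.full(4, 1.0 / 24.0)
        return pts, w
    n = (order + 2) // 2 + 1
    x, wx = np.polynomial.legendre.leggauss(n)
    u = 0.5 * (x + 1.0)
    wu = 0.5 * wx
    U, V, W = np.meshgrid(u, u, u, indexing="ij")
    WU, WV, WW = np.meshgrid(wu, wu, wu, indexing="ij")
    xi = U
    eta = V * (1.0 - U)
    zeta = W * (1.0 - U) * (1.0 - V)
    jac = (1.0 - U) ** 2 * (1.0 - V)
    pts = np.stack([xi.ravel(), eta.ravel(), zeta.ravel()], axis=1)
    w = (WU * WV * WW * jac).ravel()
    return pts, w


def reference_mass_integrals() -> np.ndarray:
    """Exact integral of N_a * N_b over the reference tet, (10, 10).

    Uses exact integration of barycentric monomials:
    int lam0^a lam1^b lam2^c lam3^d dV = a! b! c! d! / (a+b+c+d+3)! * 6V,
    with V = 1/6 for the reference tet.
    """
    from math import factorial

    # each shape function as dict {multi-index over lam: coeff}
    polys = []
    for a in range(4):
        e1 = [0, 0, 0, 0]
        e1[a] = 2
        e2 = [0, 0, 0, 0]
        e2[a] = 1
        polys.append({tuple(e1): 2.0, tuple(e2): -1.0})
    for (i, j) in EDGES:
        e = [0, 0, 0, 0]
        e[i] += 1
        e[j] += 1
        polys.append({tuple(e): 4.0})

    def integral(mi):
        num = 1.0
        for m in mi:
            num *= factorial(m)
        return num / factorial(sum(mi) + 3)

    M = np.zeros((N_NODES, N_NODES))
    for p in range(N_NODES):
        for q in range(p, N_NODES):
            s = 0.0
            for mi1, c1 in polys[p].items():
                for mi2, c2 in polys[q].items():
                    mi = tuple(m1 + m2 for m1, m2 in zip(mi1, mi2))
                    s += c1 * c2 * integral(mi)
            M[p, q] = M[q, p] = s
    return M
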