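"""Mesh data model, phantom generation, red refinement and quality metrics."""
import numpy as np
import pytest

from tonguefem import (Mesh, MeshError, PhantomSpec, generate_tongue_phantom,
                       promote_tet4, quality_report, refine_uniform)
from tonguefem.phantom import ALLOWED_OVERLAPS, MUSCLE_NAMES
from tonguefem import tet10


# ------------------------------------------------------------- reference
def test_shape_functions_partition_of_unity():
    rng = np.random.default_rng(0)
    pts = rng.dirichlet(np.ones(4), size=40)[:, 1:]  # interior points
    N = tet10.shape_functions(pts)
    np.testing.assert_allclose(N.sum(axis=1), 1.0, atol=1e-13)
    dN = tet10.shape_gradients(pts)
    np.testing.assert_allclose(dN.sum(axis=1), 0.0, atol=1e-12)


def test_shape_gradients_match_finite_differences():
    rng = np.random.default_rng(1)
    p = rng.dirichlet(np.ones(4))[1:]
    dN = tet10.shape_gradients(p)[0]
    h = 1e-7
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = h
        fd = (tet10.shape_functions(p + dp) - tet10.shape_functions(p - dp)) \
            / (2 * h)
        np.testing.assert_allclose(dN[:, k], fd[0], atol=1e-6)


@pytest.mark.parametrize("order", [2, 4, 5])
def test_quadrature_integrates_monomials(order):
    pts, w = tet10.quadrature(order)
    assert w.sum() == pytest.approx(1.0 / 6.0, rel=1e-13)
    # exactness on monomials up to the stated degree:
    # int x^a y^b z^c over ref tet = a! b! c! / (a+b+c+3)!
    from math import factorial
    for (a, b, c) in ((1, 0, 0), (0, 1, 1), (2, 0, 0), (1, 1, 0)):
        if a + b + c > order:
            continue
        exact = factorial(a) * factorial(b) * factorial(c) \
            / factorial(a + b + c + 3)
        got = (w * pts[:, 0] ** a * pts[:, 1] ** b * pts[:, 2] ** c).sum()
        assert got == pytest.approx(exact, rel=1e-12)


def test_reference_mass_integrals_sum_to_volume():
    M = tet10.reference_mass_integrals()
    assert M.sum() == pytest.approx(1.0 / 6.0, rel=1e-13)
    np.testing.assert_allclose(M, M.T)
    # classic closed-form entries for the straight-edged TET10 (x 6V):
    # vertex self-term V/420, edge self-term 4V/315
    assert M[0, 0] == pytest.approx(1.0 / 420.0, rel=1e-12)
    assert M[4, 4] == pytest.approx(4.0 / 315.0, rel=1e-12)


# ------------------------------------------------------------------ mesh
def test_mesh_validation_catches_bad_meshes(single_tet):
    single_tet.validate()
    bad = Mesh(single_tet.node_coords.copy(),
               single_tet.tet10_connectivity.copy())
    bad.node_coords[4] += 1.0  # midside node off the edge midpoint
    with pytest.raises(MeshError):
        bad.validate()
    inverted = Mesh(single_tet.node_coords,
                    single_tet.tet10_connectivity[:, [0, 2, 1, 3, 6, 5, 4, 7, 9, 8]])
    with pytest.raises(MeshError):
        inverted.validate()


def test_promote_tet4_midpoints(single_tet):
    conn = single_tet.tet10_connectivity[0]
    X = single_tet.node_coords
    for k, (i, j) in enumerate(tet10.EDGES):
        np.testing.assert_allclose(X[conn[4 + k]],
                                   0.5 * (X[conn[i]] + X[conn[j]]))


# --------------------------------------------------------------- phantom
def test_phantom_muscle_sets(default_phantom):
    m = default_phantom
    owners = {}
    for name in MUSCLE_NAMES:
        assert len(m.element_sets[name]) > 0, name
        assert len(m.fiber_fields[name]) == len(m.element_sets[name])
        norms = np.linalg.norm(m.fiber_fields[name], axis=1)
        assert np.abs(norms - 1.0).max() < 1e-12
        for e in m.element_sets[name]:
            owners.setdefault(int(e), []).append(name)
    for e, names in owners.items():
        assert len(names) <= 2
        if len(names) == 2:
            assert frozenset(names) in ALLOWED_OVERLAPS


def test_phantom_resolution_scaling(default_phantom):
    fine = generate_tongue_phantom(
        PhantomSpec(resolution=PhantomSpec().resolution / 2))
    ratio = fine.n_elements / default_phantom.n_elements
    assert 4.0 <= ratio <= 12.0


def test_phantom_determinism(default_phantom):
    again = generate_tongue_phantom(PhantomSpec())
    np.testing.assert_array_equal(again.node_coords,
                                  default_phantom.node_coords)
    np.testing.assert_array_equal(again.tet10_connectivity,
                                  default_phantom.tet10_connectivity)


def test_phantom_mirror_symmetry(default_phantom):
    z = default_phantom.node_coords[:, 2]
    key_pos = default_phantom.node_coords[z > 1e-9]
    key_neg = default_phantom.node_coords[z < -1e-9] * [1, 1, -1]
    assert len(key_pos) == len(key_neg)
    srt = lambda a: a[np.lexsort(a.T)]
    np.testing.assert_array_equal(srt(key_pos), srt(key_neg))


def test_phantom_required_sets_and_landmarks(default_phantom):
    for name in ("floor_fixed", "apex", "hyoid_attachment",
                 "mandible_attachment"):
        assert len(default_phantom.node_sets[name]) > 0
    n_vertex = default_phantom.metadata["n_vertex_nodes"]
    for name in ("landmark_apical", "landmark_alveolar", "landmark_velar",
                 "landmark_pharyngeal"):
        ids = default_phantom.node_sets[name]
        assert len(ids) == 1
        assert ids[0] < n_vertex  # vertex node: traceable across refinement
    # apical in front of velar, pharyngeal at the back
    X = default_phantom.node_coords
    assert X[default_phantom.node_sets["landmark_apical"][0], 0] > \
        X[default_phantom.node_sets["landmark_velar"][0], 0] > \
        X[default_phantom.node_sets["landmark_pharyngeal"][0], 0]


def test_phantom_degenerate_spec_errors():
    with pytest.raises(ValueError):
        generate_tongue_phantom(PhantomSpec(length=-1.0))
    with pytest.raises(ValueError):
        generate_tongue_phantom(PhantomSpec(resolution=0.0))
    with pytest.raises(MeshError):
        generate_tongue_phantom(PhantomSpec(resolution=40.0))


def test_half_phantom(half_phantom):
    assert (half_phantom.node_coords[:, 2] > -1e-12).all()
    mid = half_phantom.node_sets["midsagittal"]
    assert len(mid) > 0
    assert np.abs(half_phantom.node_coords[mid, 2]).max() < 1e-9


# ---------------------------------------------------------------- refine
def test_refine_single_tet_counts(single_tet):
    child, info = refine_uniform(single_tet)
    assert child.n_elements == 8
    assert child.n_nodes == 35  # enumeration: 10 parent + 25 new midsides
    np.testing.assert_array_equal(info["node_map"], np.arange(10))


def test_refine_volume_conservation(single_tet, coarse_phantom):
    for mesh in (single_tet, coarse_phantom):
        child, _ = refine_uniform(mesh)
        assert child.volumes().min() > 0
        assert child.volumes().sum() == pytest.approx(
            mesh.volumes().sum(), rel=1e-10)


def test_refine_preserves_landmarks_and_extends_floor(coarse_phantom):
    child, _ = refine_uniform(coarse_phantom)
    for name in ("landmark_apical", "landmark_velar"):
        nid = coarse_phantom.node_sets[name][0]
        assert child.node_sets[name][0] == nid
        np.testing.assert_array_equal(child.node_coords[nid],
                                      coarse_phantom.node_coords[nid])
    # the fixed floor gains the midside nodes of floor edges
    floor_p = coarse_phantom.node_sets["floor_fixed"]
    floor_c = child.node_sets["floor_fixed"]
    assert len(floor_c) > len(floor_p)
    assert np.abs(child.node_coords[floor_c, 1]).max() < 1e-9


def test_refine_inherits_partition(coarse_phantom):
    """Muscle partition of the refined mesh restricted to parent elements
    equals the parent partition."""
    child, info = refine_uniform(coarse_phantom)
    for name in MUSCLE_NAMES:
        parents = set(np.asarray(coarse_phantom.element_sets[name]))
        child_ids = np.asarray(child.element_sets[name])
        back = set(child_ids // 8)
        assert back == parents
        np.testing.assert_array_equal(
            child.fiber_fields[name],
            np.repeat(coarse_phantom.fiber_fields[name], 8, axis=0))


# --------------------------------------------------------------- quality
def test_quality_regular_tet():
    a = 2.0
    nodes = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0],
                      [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2.0 / 3)]])
    coords, conn = promote_tet4(nodes, np.array([[0, 1, 2, 3]]))
    rep = quality_report(Mesh(coords, conn))
    assert rep.aspect_ratio[0] == pytest.approx(1.0, rel=1e-9)
    assert rep.corner_jacobian[0] == pytest.approx(1.0, rel=1e-9)
    assert rep.size[0] == pytest.approx(a, rel=1e-12)


def test_quality_sliver():
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 1e-3]])
    coords, conn = promote_tet4(nodes, np.array([[0, 1, 2, 3]]))
    rep = quality_report(Mesh(coords, conn))
    assert rep.corner_jacobian[0] < 0.05
    assert rep.aspect_ratio[0] > 10.0


def test_quality_phantom_dispersion(default_phantom):
    rep = quality_report(default_phantom)
    assert rep.size.std() / rep.size.mean() < 0.5
    assert rep.metadata["size_definition"]
    for hist in rep.histograms.values():
        assert hist["counts"].sum() == default_phantom.n_elements
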