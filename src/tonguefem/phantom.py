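"""Synthetic tongue phantom: a parametric, mirror-symmetric TET10 solid.

The phantom is a geometric idealization of a tongue at rest — a half
ellipsoid-like solid with a flat inferior face (mouth floor), a convex
superior face (dorsum) and an anterior taper (apex) — carrying named node
sets (landmarks, attachments) and element sets for 12 muscles with
per-element unit fiber directions.  It makes no claim of anatomical
fidelity: muscle regions are centroid-rule idealizations of the classical
extrinsic/intrinsic tongue muscle topology.

Coordinate convention: X front(+)/back(-), Y up(+)/down(-), Z lateral;
mid-sagittal plane is Z = 0; units are millimeters.  The mesh is exactly
symmetric in Z (built on a half grid and mirrored).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import Mesh, MeshError, promote_tet4

MUSCLE_NAMES = ("GGa", "GGm", "GGp", "GGh", "SG", "HG", "Vert", "Trans",
                "IL", "SL", "GH", "MH")

#: muscle pairs that may share elements (interdigitating fibers)
ALLOWED_OVERLAPS = frozenset({frozenset({"Trans", "Vert"})})

#: vertical blend added to the unit radial chord of anterior-Genioglossus
#: fibers (they insert near-vertically into the blade/tip)
GGA_VERTICAL_BLEND = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic tongue phantom.

    ``resolution`` is the target element size in mm.  The Genioglossus fan is
    delimited by ``sector_angles`` (degrees above the posterior horizontal
    through the genial-tubercle analog): GGp up to the first angle, GGm up to
    the second, GGa beyond; GGh lies below the quasi-horizontal tendon plane.
    """
    length: float = 75.0            # mm, back-to-apex extent (X)
    width: float = 50.0             # mm, maximal lateral extent (Z)
    height: float = 40.0            # mm, maximal dorsum height (Y)
    resolution: float = 7.5         # mm, target element size (default phantom
                                    # has ~3000 TET10 nodes)
    seed: int = 0
    sector_angles: tuple = (55.0, 100.0)   # degrees from horizontal
    tendon_height_frac: float = 0.28       # tendon plane height / height
    fan_origin_frac: tuple = (0.80, 0.08)  # genial origin at (frac of L, frac
                                           # of H): anterior-inferior, at the
                                           # mandible (genial tubercle) level
    gg_halfwidth_frac: float = 0.30        # GG band |z| <= frac * local half width
    jitter: float = 0.0                    # mm, interior vertex jitter (seeded)
    symmetric_half: bool = False           # mesh only z >= 0; adds a
                                           # 'midsagittal' node set for the
                                           # u_z = 0 symmetry condition

    def validate(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("degenerate phantom dimensions")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        a1, a2 = self.sector_angles
        if not (0.0 < a1 < a2 < 180.0):
            raise ValueError("sector angles must satisfy 0 < a1 < a2 < 180")


# ----------------------------------------------------------------- geometry
def _half_width(spec: PhantomSpec, a: np.ndarray) -> np.ndarray:
    """Local half width w(a); a in [0,1], 0 = back, 1 = apex."""
    return 0.5 * spec.width * (1.0 - 0.55 * a ** 2)


def _top_height(spec: PhantomSpec, a: np.ndarray, zfrac: np.ndarray) -> np.ndarray:
    """Dorsum height above the floor at station a and lateral fraction zfrac."""
    profile = 0.55 + 0.45 * np.sin(np.pi * (0.12 + 0.80 * np.asarray(a)))
    taper = 1.0 - 0.45 * np.asarray(a) ** 3
    dome = 1.0 - 0.65 * np.asarray(zfrac) ** 2
    return spec.height * profile * taper * dome


def _map_box(spec: PhantomSpec, abc: np.ndarray) -> np.ndarray:
    """Map unit-box parameters (a, b, c) with c in [0, 1] (half domain,
    c = 0 on the mid-sagittal plane) to physical mm coordinates."""
    a, b, c = abc[:, 0], abc[:, 1], abc[:, 2]
    x = (a - 0.5) * spec.length
    z = c * _half_width(spec, a)
    y = b * _top_height(spec, a, c)
    return np.stack([x, y, z], axis=1)


_KUHN_TETS = (
    (0, 1, 3, 7), (0, 1, 7, 5), (0, 5, 7, 4),
    (0, 2, 7, 3), (0, 2, 6, 7), (0, 6, 4, 7),
)
# corner offsets (i, j, k) -> local id 4*i + 2*j + k is NOT used; see _corner


def _corner_ids(i, j, k, ni, nj, nk):
    """Grid vertex flat index for cell corner offsets (8,) in Kuhn order.

    Local corner numbering: bit0 = +a, bit1 = +b, bit2 = +c, i.e.
    corner n = (i + n&1, j + (n>>1)&1, k + (n>>2)&1).
    """
    ids = []
    for n in range(8):
        ii = i + (n & 1)
        jj = j + ((n >> 1) & 1)
        kk = k + ((n >> 2) & 1)
        ids.append((ii * (nj + 1) + jj) * (nk + 1) + kk)
    return ids


def _half_grid(spec: PhantomSpec):
    """Vertex nodes and tet4 connectivity of the half (z >= 0) phantom."""
    ni = max(3, int(round(spec.length / spec.resolution)))
    nj = max(1, int(round(spec.height / spec.resolution)))
    nk = max(1, int(round(0.5 * spec.width / spec.resolution)))
    av = np.linspace(0.0, 1.0, ni + 1)
    bv = np.linspace(0.0, 1.0, nj + 1)
    cv = np.linspace(0.0, 1.0, nk + 1)
    A, B, C = np.meshgrid(av, bv, cv, indexing="ij")
    abc = np.stack([A.ravel(), B.ravel(), C.ravel()], axis=1)
    nodes = _map_box(spec, abc)
    tets = []
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                cid = _corner_ids(i, j, k, ni, nj, nk)
                for t in _KUHN_TETS:
                    tets.append([cid[t[0]], cid[t[1]], cid[t[2]], cid[t[3]]])
    tets = np.array(tets, dtype=np.int64)
    # enforce positive orientation
    v = nodes[tets]
    vol = np.einsum("ei,ei->e",
                    np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                    v[:, 3] - v[:, 0]) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return nodes, tets


def _mirror(nodes: np.ndarray, tets: np.ndarray):
    """Mirror a z >= 0 half mesh through the mid-sagittal plane."""
    on_plane = np.abs(nodes[:, 2]) < 1e-12
    new_id = np.full(nodes.shape[0], -1, dtype=np.int64)
    new_id[on_plane] = np.where(on_plane)[0]
    off = np.where(~on_plane)[0]
    new_id[off] = nodes.shape[0] + np.arange(off.size)
    mirrored = nodes[off].copy()
    mirrored[:, 2] = -mirrored[:, 2]
    all_nodes = np.vstack([nodes, mirrored])
    mtets = new_id[tets]
    mtets = mtets[:, [0, 2, 1, 3]]  # restore orientation after reflection
    all_tets = np.vstack([tets, mtets])
    return all_nodes, all_tets


# ----------------------------------------------------------------- muscles
def _fan_angle_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Angle of (dx, dy) from the posterior horizontal (-X), degrees.

    0 deg = straight back, 90 deg = straight up, 180 deg = straight forward.
    """
    return np.degrees(np.arctan2(dy, -dx))


def _build_muscles(spec: PhantomSpec, mesh: Mesh) -> None:
    cent = mesh.element_centroids()
    L, W, H = spec.length, spec.width, spec.height
    a = cent[:, 0] / L + 0.5
    w_loc = _half_width(spec, a)
    zfrac = np.clip(np.abs(cent[:, 2]) / w_loc, 0.0, 1.0)
    top = _top_height(spec, a, zfrac)
    rho = np.clip(cent[:, 1] / top, 0.0, 1.0)     # height fraction
    xhat = a                                       # 0 back, 1 front

    xo = (spec.fan_origin_frac[0] - 0.5) * L
    yo = spec.fan_origin_frac[1] * H
    origin = np.array([xo, yo, 0.0])
    dx = cent[:, 0] - xo
    dy = cent[:, 1] - yo
    phi = _fan_angle_deg(dx, dy)
    a1, a2 = spec.sector_angles

    gg_band = np.abs(cent[:, 2]) <= spec.gg_halfwidth_frac * w_loc
    below_tendon = cent[:, 1] < spec.tendon_height_frac * H
    ggh = gg_band & below_tendon & (cent[:, 0] < xo)
    fan = gg_band & ~ggh
    ggp = fan & (phi > 0.0) & (phi <= a1)
    ggm = fan & (phi > a1) & (phi <= a2)
    gga = fan & ((phi > a2) | (phi <= 0.0))
    gg_any = ggh | ggp | ggm | gga

    sets: dict[str, np.ndarray] = {}
    fibers: dict[str, np.ndarray] = {}

    def radial_fibers(mask):
        d = cent[mask] - origin
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def const_fibers(mask, vec):
        v = np.asarray(vec, dtype=float)
        v = v / np.linalg.norm(v)
        return np.tile(v, (int(mask.sum()), 1))

    for name, mask in (("GGp", ggp), ("GGm", ggm), ("GGa", gga)):
        sets[name] = np.where(mask)[0]
        fib = radial_fibers(mask)
        if name == "GGa":
            # the anterior fan fibers curve steeply upward to insert into
            # the blade and tip from below; blend the radial chord toward
            # vertical so contraction lowers the tip rather than dragging
            # the whole anterior body backward
            fib[:, 1] += GGA_VERTICAL_BLEND
            fib /= np.linalg.norm(fib, axis=1, keepdims=True)
        fibers[name] = fib
    sets["GGh"] = np.where(ggh)[0]
    fibers["GGh"] = const_fibers(ggh, (-1.0, 0.0, 0.0))

    # Non-GG muscles partition the remaining volume by height fraction rho,
    # lateral fraction zfrac and longitudinal fraction xhat (disjoint by
    # construction, except the declared Vert/Trans interdigitation).
    floor_layer = ~gg_band & (rho < 0.30)
    medial = zfrac <= 0.55

    # Geniohyoid: central floor strip (genial tubercle to hyoid).
    gh = floor_layer & medial & (xhat > 0.05) & (xhat < 0.90)
    sets["GH"] = np.where(gh)[0]
    fibers["GH"] = const_fibers(gh, (1.0, 0.0, 0.0))

    # Mylohyoid: lateral floor sheet, sling-like fibers (medially and up).
    mh = floor_layer & ~medial
    sets["MH"] = np.where(mh)[0]
    side = np.sign(cent[mh][:, 2])
    v = np.stack([np.zeros(side.shape), 0.35 * np.ones(side.shape), -side], axis=1)
    fibers["MH"] = v / np.linalg.norm(v, axis=1, keepdims=True)

    # Superior Longitudinalis: layer under the dorsum (medial), fibers along
    # the local sagittal tangent of the dorsum surface.
    sl = ~gg_band & medial & (rho >= 0.72) & (xhat > 0.05)
    sets["SL"] = np.where(sl)[0]
    eps = 1e-3
    dtop = (_top_height(spec, a[sl] + eps, zfrac[sl])
            - _top_height(spec, a[sl] - eps, zfrac[sl])) / (2 * eps * L)
    t = np.stack([np.ones(int(sl.sum())), dtop, np.zeros(int(sl.sum()))], axis=1)
    fibers["SL"] = t / np.linalg.norm(t, axis=1, keepdims=True)

    # Styloglossus: lateral-dorsal band, fibers toward a virtual styloid
    # process (posterior-superior-lateral, outside the mesh, per side).
    sg = ~gg_band & ~floor_layer & ~medial & (rho >= 0.50) & \
        (xhat > 0.10) & (xhat < 0.97)
    sets["SG"] = np.where(sg)[0]
    side = np.sign(cent[sg][:, 2])
    styloid = np.stack([np.full(side.shape, -0.60 * L),
                        np.full(side.shape, 1.40 * H),
                        side * 0.85 * 0.5 * W], axis=1)
    d = styloid - cent[sg]
    # the SG courses longitudinally along the lateral dorsum; only its
    # external branches turn up toward the styloid, so the in-body fiber
    # direction keeps a damped vertical component
    d[:, 1] *= 0.35
    fibers["SG"] = d / np.linalg.norm(d, axis=1, keepdims=True)

    # Hyoglossus: posterior-lateral sheet, fibers from the hyoid corner
    # (posterior-inferior) up and forward into the body.
    hg = ~gg_band & ~floor_layer & ~medial & (rho < 0.50) & (xhat < 0.40)
    sets["HG"] = np.where(hg)[0]
    side = np.sign(cent[hg][:, 2])
    hyoid_pt = np.stack([np.full(side.shape, -0.48 * L),
                         np.full(side.shape, -0.05 * H),
                         side * 0.55 * 0.5 * W], axis=1)
    d = cent[hg] - hyoid_pt
    fibers["HG"] = d / np.linalg.norm(d, axis=1, keepdims=True)

    # Inferior Longitudinalis: inferior-lateral band running front-back.
    il = ~gg_band & ~floor_layer & ~medial & (rho < 0.50) & \
        (xhat >= 0.40) & (xhat < 0.95)
    sets["IL"] = np.where(il)[0]
    fibers["IL"] = const_fibers(il, (1.0, 0.0, 0.0))

    # Verticalis / Transversalis: interdigitating medial body core (declared
    # two-muscle overlap pair), vertical and transverse fibers.
    core = ~gg_band & medial & (rho >= 0.30) & (rho < 0.72)
    vert = core & (xhat > 0.35)
    trans = core & (xhat > 0.15)
    sets["Vert"] = np.where(vert)[0]
    fibers["Vert"] = const_fibers(vert, (0.0, 1.0, 0.0))
    sets["Trans"] = np.where(trans)[0]
    fibers["Trans"] = const_fibers(trans, (0.0, 0.0, 1.0))

    empty = [name for name in MUSCLE_NAMES if sets[name].size == 0]
    mesh.element_sets.update(sets)
    mesh.fiber_fields.update(fibers)
    return empty


def _check_overlaps(mesh: Mesh) -> None:
    owner: dict[int, list[str]] = {}
    for name in MUSCLE_NAMES:
        for e in mesh.element_sets[name]:
            owner.setdefault(int(e), []).append(name)
    for e, names in owner.items():
        if len(names) > 2:
            raise MeshError(f"element {e} in >2 muscle sets: {names}")
        if len(names) == 2 and frozenset(names) not in ALLOWED_OVERLAPS:
            raise MeshError(f"undeclared muscle overlap on element {e}: {names}")


# ---------------------------------------------------------------- node sets
def _build_node_sets(spec: PhantomSpec, mesh: Mesh, n_vertex: int) -> None:
    X = mesh.node_coords
    L, H = spec.length, spec.height
    surf = mesh.surface_node_ids()
    floor = surf[np.abs(X[surf, 1]) < 1e-9]
    fx = X[floor, 0] / L + 0.5
    mesh.node_sets["hyoid_attachment"] = floor[fx < 0.18]
    mesh.node_sets["mandible_attachment"] = floor[fx > 0.82]
    mesh.node_sets["floor_fixed"] = floor[(fx >= 0.18) & (fx <= 0.82)]
    front = surf[X[surf, 0] > 0.5 * L - 1e-9]
    mesh.node_sets["apex"] = front

    # Styloglossus insertion patches: posterior-superior-lateral surface
    # nodes where the external SG branches (cables to the virtual styloid
    # processes) attach
    sx = X[surf, 0] / L + 0.5
    w_here = _half_width(spec, np.clip(sx, 0, 1))
    szfrac = np.abs(X[surf, 2]) / np.maximum(w_here, 1e-9)
    stop = _top_height(spec, np.clip(sx, 0, 1), np.clip(szfrac, 0, 1))
    srho = X[surf, 1] / np.maximum(stop, 1e-9)
    sg_patch = (sx < 0.35) & (szfrac > 0.45) & (srho > 0.55)
    right = surf[sg_patch & (X[surf, 2] > 0)]
    left = surf[sg_patch & (X[surf, 2] < 0)]
    if right.size:
        mesh.node_sets["sg_insertion_right"] = right
    if left.size:
        mesh.node_sets["sg_insertion_left"] = left

    # Landmarks: single vertex nodes (traceable across red refinement)
    # nearest to phonetically meaningful mid-sagittal surface targets.
    targets = {
        "landmark_apical": (0.50 * L, 0.5 * _top_height(spec, 1.0, 0.0), 0.0),
        "landmark_alveolar": (0.30 * L, _top_height(spec, 0.80, 0.0), 0.0),
        "landmark_velar": (-0.22 * L, _top_height(spec, 0.28, 0.0), 0.0),
        "landmark_pharyngeal": (-0.50 * L, 0.55 * _top_height(spec, 0.0, 0.0), 0.0),
    }
    # landmarks live on the free surface: floor (fixed / attachment) nodes
    # are excluded so coarse meshes cannot pin a landmark to a constraint
    surf_vertices = surf[(surf < n_vertex) & (X[surf, 1] > 1e-9)]
    for name, tgt in targets.items():
        d = np.linalg.norm(X[surf_vertices] - np.asarray(tgt), axis=1)
        mesh.node_sets[name] = np.array([surf_vertices[int(np.argmin(d))]])


def _build_surface_sets(spec: PhantomSpec, mesh: Mesh) -> None:
    faces = mesh.boundary_faces()
    fc = mesh.node_coords[faces[:, :3]].mean(axis=1)
    a = fc[:, 0] / spec.length + 0.5
    top = _top_height(spec, a, np.clip(np.abs(fc[:, 2]) / _half_width(spec, a), 0, 1))
    mesh.surface_sets["floor"] = faces[np.abs(fc[:, 1]) < 1e-9]
    mesh.surface_sets["dorsum"] = faces[fc[:, 1] > 0.75 * top]


# ------------------------------------------------------------------- entry
def generate_tongue_phantom(spec: PhantomSpec | None = None, *,
                            require_muscles: bool = True) -> Mesh:
    """Generate the synthetic tongue phantom mesh for ``spec``.

    Pure function of the spec (including its seed); repeated calls return
    bitwise-identical meshes.  With ``require_muscles`` (the default), a
    resolution too coarse to host at least one element in every muscle set
    is an error; convergence studies that only need the passive geometry
    may disable the check.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    nodes4, tets4 = _half_grid(spec)
    if not spec.symmetric_half:
        nodes4, tets4 = _mirror(nodes4, tets4)
    if spec.jitter > 0.0:
        nodes4 = _apply_jitter(spec, nodes4, tets4)
    n_vertex = nodes4.shape[0]
    coords, conn = promote_tet4(nodes4, tets4)
    mesh = Mesh(coords, conn, metadata={
        "phantom_spec": {k: getattr(spec, k) for k in (
            "length", "width", "height", "resolution", "seed",
            "sector_angles", "tendon_height_frac", "fan_origin_frac",
            "gg_halfwidth_frac", "jitter")},
        "n_vertex_nodes": n_vertex,
    })
    mesh.validate()
    empty = _build_muscles(spec, mesh)
    if empty and require_muscles:
        raise MeshError(
            f"resolution {spec.resolution} mm too coarse: empty muscle "
            f"sets {empty}")
    _check_overlaps(mesh)
    _build_node_sets(spec, mesh, n_vertex)
    _build_surface_sets(spec, mesh)
    if spec.symmetric_half:
        mesh.node_sets["midsagittal"] = np.where(
            np.abs(mesh.node_coords[:, 2]) < 1e-9)[0]
    return mesh


def styloglossus_cables(spec: PhantomSpec, stiffness_n_per_mm: float = 0.002):
    """Contractile-cable stand-ins for the external Styloglossus branches.

    Returns spring entries (node_set, anchor_mm, stiffness N/mm per node,
    muscle) pulling the SG insertion patches toward virtual styloid
    processes (posterior-superior-lateral, outside the mesh); the cable
    force scales with the SG activation.
    """
    L, W, H = spec.length, spec.width, spec.height
    out = [("sg_insertion_right", (-0.60 * L, 1.40 * H, 0.85 * 0.5 * W),
            stiffness_n_per_mm, "SG")]
    if not spec.symmetric_half:
        out.append(("sg_insertion_left", (-0.60 * L, 1.40 * H, -0.85 * 0.5 * W),
                    stiffness_n_per_mm, "SG"))
    return out


def _apply_jitter(spec: PhantomSpec, nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Seeded interior-vertex jitter, applied symmetrically in Z."""
    rng = np.random.default_rng(spec.seed)
    half = nodes[:, 2] >= -1e-12
    # jitter only strictly interior nodes of the half mesh, then mirror
    from .mesh import Mesh as _M
    probe = _M(nodes, promote_tet4(nodes, tets)[1])
    interior = np.setdiff1d(np.arange(nodes.shape[0]), probe.surface_node_ids())
    out = nodes.copy()
    for nid in interior:
        if not half[nid]:
            continue
        d = rng.normal(scale=spec.jitter, size=3)
        out[nid] += d
        # find mirror partner
        m = np.where((np.abs(nodes[:, 0] - nodes[nid, 0]) < 1e-9)
                     & (np.abs(nodes[:, 1] - nodes[nid, 1]) < 1e-9)
                     & (np.abs(nodes[:, 2] + nodes[nid, 2]) < 1e-9))[0]
        for pm in m:
            if pm != nid:
                out[pm] = out[nid] * np.array([1.0, 1.0, -1.0])
    return out
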