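"""Uniform red (1:8) refinement of TET10 meshes.

Every parent tetrahedron is split by its edge midpoints into 8 children:
4 corner tets plus 4 tets from the interior octahedron, which is cut along
its shortest diagonal (a geometric, mirror-symmetric choice).  All parent
nodes — vertices and midside nodes alike — become vertex nodes of the child
mesh and keep their indices, so landmark node sets remain valid across
refinement levels.
"""
from __future__ import annotations

import numpy as np

from .mesh import Mesh, MeshError, promote_tet4
from . import tet10


def _child_tets(conn: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """(E, 8, 4) child vertex connectivity from parent TET10 connectivity."""
    v0, v1, v2, v3 = conn[:, 0], conn[:, 1], conn[:, 2], conn[:, 3]
    m01, m12, m02, m03, m13, m23 = (conn[:, 4 + k] for k in range(6))
    E = conn.shape[0]
    out = np.empty((E, 8, 4), dtype=np.int64)
    out[:, 0] = np.stack([v0, m01, m02, m03], axis=1)
    out[:, 1] = np.stack([m01, v1, m12, m13], axis=1)
    out[:, 2] = np.stack([m02, m12, v2, m23], axis=1)
    out[:, 3] = np.stack([m03, m13, m23, v3], axis=1)
    # octahedron (m01, m12, m02, m03, m13, m23): pick the shortest of the
    # three diagonals m01-m23, m12-m03, m02-m13
    d1 = np.linalg.norm(coords[m01] - coords[m23], axis=1)
    d2 = np.linalg.norm(coords[m12] - coords[m03], axis=1)
    d3 = np.linalg.norm(coords[m02] - coords[m13], axis=1)
    choice = np.argmin(np.stack([d1, d2, d3], axis=1), axis=1)
    # tets around each diagonal (consistent positive orientation fixed below)
    octs = {
        0: [(m01, m23, m02, m03), (m01, m23, m03, m13),
            (m01, m23, m13, m12), (m01, m23, m12, m02)],
        1: [(m12, m03, m01, m02), (m12, m03, m02, m23),
            (m12, m03, m23, m13), (m12, m03, m13, m01)],
        2: [(m02, m13, m01, m03), (m02, m13, m03, m23),
            (m02, m13, m23, m12), (m02, m13, m12, m01)],
    }
    for c, tets in octs.items():
        mask = choice == c
        for t in range(4):
            out[mask, 4 + t] = np.stack(tets[t], axis=1)[mask]
    # orientation fix per child
    v = coords[out.reshape(-1, 4)]
    vol = np.einsum("ei,ei->e",
                    np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                    v[:, 3] - v[:, 0]) / 6.0
    flat = out.reshape(-1, 4)
    flip = vol < 0
    flat[flip] = flat[flip][:, [0, 2, 1, 3]]
    if np.any(vol == 0):
        raise MeshError("red refinement produced a degenerate child element")
    return flat.reshape(E, 8, 4)


def refine_uniform(mesh: Mesh) -> tuple[Mesh, dict]:
    """Red-refine a TET10 mesh.

    Returns (child_mesh, info) where ``info['node_map']`` maps parent node
    ids to child node ids (the identity: parent nodes keep their indices),
    ``info['element_children']`` maps parent element e to child ids
    ``8*e .. 8*e+7``, and ``info['new_node_edges']`` gives the two parent
    node ids spanning the edge of each appended midside node.

    Node sets are extended: a new midside node joins every set that contains
    both of its edge endpoints, so region constraints (e.g. the fixed mouth
    floor) stay geometrically consistent across refinement levels.
    """
    child4 = _child_tets(mesh.tet10_connectivity, mesh.node_coords)
    E = mesh.n_elements
    coords, conn, new_edges = promote_tet4(mesh.node_coords,
                                           child4.reshape(-1, 4),
                                           return_edges=True)
    vols = Mesh(coords, conn).volumes()
    if np.any(vols <= 0):
        raise MeshError(f"inverted child elements: {np.where(vols <= 0)[0][:10].tolist()}")

    n_parent = mesh.n_nodes
    node_sets = {}
    for name, ids in mesh.node_sets.items():
        ids = np.asarray(ids)
        member = np.zeros(n_parent, dtype=bool)
        member[ids] = True
        if new_edges.size:
            both = member[new_edges[:, 0]] & member[new_edges[:, 1]]
            extra = n_parent + np.where(both)[0]
            node_sets[name] = np.concatenate([ids, extra])
        else:
            node_sets[name] = ids.copy()

    child = Mesh(coords, conn, node_sets=node_sets,
                 metadata=dict(mesh.metadata))
    child.metadata["refined_from_nodes"] = mesh.n_nodes

    for name, ids in mesh.element_sets.items():
        ids = np.asarray(ids)
        child.element_sets[name] = (8 * ids[:, None] + np.arange(8)[None, :]).ravel()
        if name in mesh.fiber_fields:
            child.fiber_fields[name] = np.repeat(mesh.fiber_fields[name], 8, axis=0)

    # surface sets: split each 6-node face into 4 children, looking up the
    # new midside nodes from the child volume connectivity
    edge_mid: dict[tuple[int, int], int] = {}
    for e in range(conn.shape[0]):
        for k, (i, j) in enumerate(tet10.EDGES):
            a, b = int(conn[e, i]), int(conn[e, j])
            key = (a, b) if a < b else (b, a)
            edge_mid[key] = int(conn[e, 4 + k])

    def mid(a, b):
        return edge_mid[(a, b) if a < b else (b, a)]

    for name, faces in mesh.surface_sets.items():
        new_faces = []
        for f in np.asarray(faces):
            a, b, c, mab, mbc, mac = (int(x) for x in f)
            for tri in ((a, mab, mac), (mab, b, mbc), (mac, mbc, c), (mab, mbc, mac)):
                p, q, r = tri
                new_faces.append([p, q, r, mid(p, q), mid(q, r), mid(p, r)])
        child.surface_sets[name] = np.array(new_faces, dtype=np.int64) if new_faces \
            else np.empty((0, 6), dtype=np.int64)

    info = {
        "node_map": np.arange(mesh.n_nodes),
        "element_children": np.arange(8 * E).reshape(E, 8),
        "new_node_edges": new_edges,
    }
    return child, info
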