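"""Volumetric TET10 mesh container with named node/element/surface sets.

Coordinates are in millimeters.  Element connectivity uses the VTK
quadratic-tetra node ordering (see :mod:`tonguefem.tet10`).  Muscle fiber
fields are stored per element set: ``fiber_fields[name]`` is an array of unit
vectors parallel to ``element_sets[name]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tet10


class MeshError(ValueError):
    pass


@dataclass
class Mesh:
    node_coords: np.ndarray            # (N, 3) float, mm
    tet10_connectivity: np.ndarray     # (E, 10) int
    node_sets: dict = field(default_factory=dict)     # name -> (k,) int
    element_sets: dict = field(default_factory=dict)  # name -> (k,) int
    surface_sets: dict = field(default_factory=dict)  # name -> (F, 6) int
    fiber_fields: dict = field(default_factory=dict)  # name -> (k, 3) float unit
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.tet10_connectivity = np.asarray(self.tet10_connectivity, dtype=np.int64)
        if self.tet10_connectivity.ndim != 2 or self.tet10_connectivity.shape[1] != 10:
            raise MeshError("connectivity must be (E, 10)")

    # ------------------------------------------------------------------ sizes
    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tet10_connectivity.shape[0]

    # ------------------------------------------------------------- geometry
    def vertex_coords(self) -> np.ndarray:
        """(E, 4, 3) coordinates of the 4 corner vertices per element."""
        return self.node_coords[self.tet10_connectivity[:, :4]]

    def volumes(self) -> np.ndarray:
        """Signed volumes from corner vertices (exact for straight-edged tets)."""
        v = self.vertex_coords()
        d = v[:, 1:] - v[:, :1]
        return np.einsum("ei,ei->e", np.cross(d[:, 0], d[:, 1]), d[:, 2]) / 6.0

    def jacobians_at_quadrature(self, order: int = 2) -> np.ndarray:
        """det of the isoparametric Jacobian at each quadrature point, (E, Q)."""
        pts, _ = tet10.quadrature(order)
        dN = tet10.shape_gradients(pts)            # (Q, 10, 3)
        X = self.node_coords[self.tet10_connectivity]  # (E, 10, 3)
        J = np.einsum("eai,qaj->eqij", X, dN)      # (E, Q, 3, 3) dX/dxi
        return np.linalg.det(J)

    def mean_edge_lengths(self) -> np.ndarray:
        """Per-element mean length over the 6 vertex edges (the element 'size')."""
        v = self.vertex_coords()
        ls = []
        for i in range(4):
            for j in range(i + 1, 4):
                ls.append(np.linalg.norm(v[:, i] - v[:, j], axis=1))
        return np.mean(ls, axis=0)

    def element_centroids(self) -> np.ndarray:
        return self.vertex_coords().mean(axis=1)

    # ------------------------------------------------------------- checking
    def validate(self, curved_ok: bool = False, tol: float = 1e-9) -> None:
        """Raise MeshError on violated invariants."""
        conn = self.tet10_connectivity
        if conn.min(initial=0) < 0 or (self.n_elements and conn.max() >= self.n_nodes):
            raise MeshError("connectivity index out of range")
        if np.any(self.volumes() <= 0.0):
            bad = np.where(self.volumes() <= 0)[0]
            raise MeshError(f"non-positive element volumes: {bad[:10].tolist()}")
        if np.any(self.jacobians_at_quadrature() <= 0.0):
            raise MeshError("non-positive Jacobian at a quadrature point")
        if not curved_ok:
            X = self.node_coords
            for k, (i, j) in enumerate(tet10.EDGES):
                mid = 0.5 * (X[conn[:, i]] + X[conn[:, j]])
                err = np.abs(X[conn[:, 4 + k]] - mid).max(initial=0.0)
                if err > tol:
                    raise MeshError(f"midside node off edge midpoint by {err:g} mm")
        # unique elements (by sorted vertex ids)
        key = np.sort(conn[:, :4], axis=1)
        if len(np.unique(key, axis=0)) != self.n_elements:
            raise MeshError("duplicate elements")
        for name, ids in self.node_sets.items():
            ids = np.asarray(ids)
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise MeshError(f"node set {name!r} index out of range")
        for name, ids in self.element_sets.items():
            ids = np.asarray(ids)
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_elements):
                raise MeshError(f"element set {name!r} index out of range")
        for name, vec in self.fiber_fields.items():
            norms = np.linalg.norm(np.asarray(vec), axis=1)
            if norms.size and np.abs(norms - 1.0).max() > 1e-12:
                raise MeshError(f"fiber field {name!r} not unit length")

    # ------------------------------------------------------------ utilities
    def boundary_faces(self) -> np.ndarray:
        """All exterior faces as (F, 6) TET10 face triangles (3 vertices + 3 midsides)."""
        conn = self.tet10_connectivity
        # faces of the tet by local vertex triples with their midside nodes
        # face (i,j,k): midsides on edges (i,j), (j,k), (i,k)
        edge_index = {}
        for k, (i, j) in enumerate(tet10.EDGES):
            edge_index[(i, j)] = 4 + k
            edge_index[(j, i)] = 4 + k
        local_faces = []
        for (i, j, k) in ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)):
            local_faces.append([i, j, k, edge_index[(i, j)], edge_index[(j, k)], edge_index[(i, k)]])
        faces = np.concatenate([conn[:, lf] for lf in local_faces], axis=0)
        key = np.sort(faces[:, :3], axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def surface_node_ids(self) -> np.ndarray:
        return np.unique(self.boundary_faces())


def promote_tet4(nodes: np.ndarray, tets: np.ndarray,
                 return_edges: bool = False):
    """Insert edge-midpoint nodes into a linear tet mesh, returning TET10 data.

    Returns (node_coords, tet10_connectivity); original vertex nodes keep
    their indices, midside nodes are appended.  With ``return_edges`` a
    third value gives, for every new midside node in order, the pair of
    vertex node ids of its edge.
    """
    nodes = np.asarray(nodes, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    edge_ids: dict[tuple[int, int], int] = {}
    extra: list[np.ndarray] = []
    conn = np.empty((tets.shape[0], 10), dtype=np.int64)
    conn[:, :4] = tets
    next_id = nodes.shape[0]
    for e, tet in enumerate(tets):
        for k, (i, j) in enumerate(tet10.EDGES):
            a, b = int(tet[i]), int(tet[j])
            key = (a, b) if a < b else (b, a)
            nid = edge_ids.get(key)
            if nid is None:
                nid = next_id
                edge_ids[key] = nid
                extra.append(0.5 * (nodes[a] + nodes[b]))
                next_id += 1
            conn[e, 4 + k] = nid
    all_nodes = np.vstack([nodes, np.array(extra)]) if extra else nodes.copy()
    if return_edges:
        edges = np.array(sorted(edge_ids, key=edge_ids.get), dtype=np.int64) \
            if edge_ids else np.empty((0, 2), dtype=np.int64)
        return all_nodes, conn, edges
    return all_nodes, conn
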