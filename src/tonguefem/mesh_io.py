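"""Mesh I/O: Gmsh 4.1 ASCII, VTK .vtu (XML) export, an internal JSON
container, and triangulated rigid-surface readers (STL/OBJ).

The internal container round-trips every field of :class:`~tonguefem.mesh.Mesh`
losslessly; Gmsh files carry geometry and connectivity only (named sets do
not survive a Gmsh round-trip and their absence on read is a warning, not an
error).  Linear-tet Gmsh meshes are promoted to TET10 by midpoint insertion.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .mesh import Mesh, promote_tet4

#: VTK -> Gmsh midside permutation for the 10-node tetrahedron
_VTK_TO_GMSH = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]
_GMSH_TO_VTK = _VTK_TO_GMSH  # the permutation is an involution

_FORMATS = ("gmsh-4.1", "vtu", "internal-container")


class UnsupportedFormatError(ValueError):
    pass


def write_mesh(mesh: Mesh, path, format: str | None = None, **kwargs) -> None:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "gmsh-4.1":
        _write_gmsh(mesh, path)
    elif fmt == "vtu":
        write_vtu(mesh, path, **kwargs)
    elif fmt == "internal-container":
        _write_container(mesh, path)
    else:
        raise UnsupportedFormatError(f"unsupported mesh format {fmt!r}; "
                                     f"known: {_FORMATS}")


def read_mesh(path, format: str | None = None) -> Mesh:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "gmsh-4.1":
        return _read_gmsh(path)
    if fmt == "internal-container":
        return _read_container(path)
    raise UnsupportedFormatError(f"unsupported mesh format for reading {fmt!r}; "
                                 "known: gmsh-4.1, internal-container")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".msh": "gmsh-4.1", ".vtu": "vtu", ".json": "internal-container",
            ".tfm": "internal-container"}.get(suffix, suffix.lstrip("."))


# ------------------------------------------------------------------- gmsh
def _write_gmsh(mesh: Mesh, path: Path) -> None:
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    n = mesh.n_nodes
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 1 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.node_coords]
    lines.append("$EndNodes")
    e = mesh.n_elements
    lines += ["$Elements", f"1 {e} 1 {e}", f"3 1 11 {e}"]
    conn = mesh.tet10_connectivity[:, _VTK_TO_GMSH] + 1
    lines += [str(i + 1) + " " + " ".join(map(str, row)) for i, row in enumerate(conn)]
    lines += ["$EndElements", ""]
    path.write_text("\n".join(lines))


def _read_gmsh(path: Path) -> Mesh:
    text = Path(path).read_text().split("\n")
    it = iter(text)

    def until(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"missing {tag} section")

    until("$MeshFormat")
    version = next(it).split()[0]
    if not version.startswith("4"):
        raise UnsupportedFormatError(f"only Gmsh 4.x supported, got {version}")
    until("$Nodes")
    n_blocks, n_nodes, *_ = map(int, next(it).split())
    tags, coords = [], []
    for _ in range(n_blocks):
        _, _, _, n_in = map(int, next(it).split())
        block_tags = [int(next(it)) for _ in range(n_in)]
        block_coords = [[float(v) for v in next(it).split()[:3]] for _ in range(n_in)]
        tags += block_tags
        coords += block_coords
    tag_to_id = {t: i for i, t in enumerate(tags)}
    coords = np.array(coords)
    until("$Elements")
    n_blocks, _, *_ = map(int, next(it).split())
    tet4, tet10 = [], []
    skipped = set()
    for _ in range(n_blocks):
        _, _, etype, n_in = map(int, next(it).split())
        for _ in range(n_in):
            vals = next(it).split()
            nodes = [tag_to_id[int(v)] for v in vals[1:]]
            if etype == 4:
                tet4.append(nodes)
            elif etype == 11:
                tet10.append([nodes[p] for p in _GMSH_TO_VTK])
            else:
                skipped.add(etype)
    if skipped:
        warnings.warn(f"ignored Gmsh element types {sorted(skipped)}")
    if tet10 and tet4:
        raise ValueError("mixed tet4/tet10 meshes are not supported")
    if tet10:
        mesh = Mesh(coords, np.array(tet10, dtype=np.int64))
    elif tet4:
        nodes, conn = promote_tet4(coords, np.array(tet4, dtype=np.int64))
        mesh = Mesh(nodes, conn)
    else:
        raise ValueError("no tetrahedral elements in file")
    warnings.warn("Gmsh files carry no named node/element sets; "
                  "sets are empty after read")
    return mesh


# -------------------------------------------------------------------- vtu
def write_vtu(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write a VTK XML unstructured grid with quadratic tetra cells (type 24).

    ``point_data`` maps names to (N,) or (N, 3) arrays (e.g. displacements,
    mm); ``cell_data`` maps names to (E,) arrays.  A ``muscle`` cell array
    with the index of each element's first muscle (-1 if none, order of
    sorted muscle-set names) is always included when muscle sets exist.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    muscle_names = sorted(n for n in mesh.fiber_fields)
    if muscle_names and "muscle" not in cell_data:
        label = np.full(mesh.n_elements, -1, dtype=np.int64)
        for idx, name in enumerate(muscle_names):
            label[np.asarray(mesh.element_sets[name])] = idx
        cell_data["muscle"] = label

    def arr_block(name, data, indent):
        data = np.asarray(data)
        comps = 1 if data.ndim == 1 else data.shape[1]
        dtype = "Float64" if np.issubdtype(data.dtype, np.floating) else "Int64"
        flat = data.reshape(-1)
        body = "\n".join(" ".join(f"{v:.17g}" if dtype == "Float64" else str(int(v))
                                  for v in flat[i:i + 6])
                         for i in range(0, flat.size, 6))
        pad = " " * indent
        return (f'{pad}<DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{comps}" format="ascii">\n{body}\n{pad}</DataArray>')

    n, e = mesh.n_nodes, mesh.n_elements
    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             '  <UnstructuredGrid>',
             f'    <Piece NumberOfPoints="{n}" NumberOfCells="{e}">']
    if point_data:
        parts.append('      <PointData>')
        for k, v in point_data.items():
            parts.append(arr_block(k, v, 8))
        parts.append('      </PointData>')
    if cell_data:
        parts.append('      <CellData>')
        for k, v in cell_data.items():
            parts.append(arr_block(k, v, 8))
        parts.append('      </CellData>')
    parts.append('      <Points>')
    parts.append(arr_block("Points", mesh.node_coords, 8))
    parts.append('      </Points>')
    parts.append('      <Cells>')
    parts.append(arr_block("connectivity", mesh.tet10_connectivity.ravel(), 8))
    parts.append(arr_block("offsets", 10 * (np.arange(e) + 1), 8))
    parts.append(arr_block("types", np.full(e, 24, dtype=np.int64), 8))
    parts.append('      </Cells>')
    parts += ['    </Piece>', '  </UnstructuredGrid>', '</VTKFile>', '']
    Path(path).write_text("\n".join(parts))


# -------------------------------------------------------- internal container
def _write_container(mesh: Mesh, path: Path) -> None:
    def clean_meta(obj):
        if isinstance(obj, dict):
            return {k: clean_meta(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean_meta(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    doc = {
        "format": "tonguefem-mesh",
        "version": 1,
        "node_coords": mesh.node_coords.tolist(),
        "tet10_connectivity": mesh.tet10_connectivity.tolist(),
        "node_sets": {k: np.asarray(v).tolist() for k, v in mesh.node_sets.items()},
        "element_sets": {k: np.asarray(v).tolist() for k, v in mesh.element_sets.items()},
        "surface_sets": {k: np.asarray(v).tolist() for k, v in mesh.surface_sets.items()},
        "fiber_fields": {k: np.asarray(v).tolist() for k, v in mesh.fiber_fields.items()},
        "metadata": clean_meta(mesh.metadata),
    }
    Path(path).write_text(json.dumps(doc))


def _read_container(path: Path) -> Mesh:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "tonguefem-mesh":
        raise UnsupportedFormatError("not a tonguefem mesh container")
    return Mesh(
        np.array(doc["node_coords"], dtype=float),
        np.array(doc["tet10_connectivity"], dtype=np.int64),
        node_sets={k: np.array(v, dtype=np.int64) for k, v in doc["node_sets"].items()},
        element_sets={k: np.array(v, dtype=np.int64) for k, v in doc["element_sets"].items()},
        surface_sets={k: np.array(v, dtype=np.int64).reshape(-1, 6)
                      for k, v in doc["surface_sets"].items()},
        fiber_fields={k: np.array(v, dtype=float).reshape(-1, 3)
                      for k, v in doc["fiber_fields"].items()},
        metadata=doc.get("metadata", {}),
    )


# ------------------------------------------------------------ rigid surfaces
def read_surface(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a triangulated surface (ASCII STL or Wavefront OBJ).

    Returns (vertices (V, 3) mm, triangles (T, 3) int).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        return _read_stl(path)
    if suffix == ".obj":
        return _read_obj(path)
    raise UnsupportedFormatError(f"unsupported surface format {suffix!r}")


def _read_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    head = path.read_bytes()[:512]
    try:
        is_ascii = head.lstrip().lower().startswith(b"solid") and b"facet" in head
    except Exception:
        is_ascii = False
    if not is_ascii:
        raise UnsupportedFormatError("only ASCII STL is supported")
    verts: list[tuple] = []
    index: dict[tuple, int] = {}
    tris = []
    current: list[int] = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "vertex":
            v = tuple(float(x) for x in parts[1:4])
            vid = index.setdefault(v, len(verts))
            if vid == len(verts):
                verts.append(v)
            current.append(vid)
        elif parts[0] == "endfacet":
            if len(current) == 3:
                tris.append(current)
            current = []
    return np.array(verts, dtype=float), np.array(tris, dtype=np.int64)


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, tris = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            ids = [int(p.split("/")[0]) - 1 for p in parts[1:]]
            for k in range(1, len(ids) - 1):  # fan triangulation
                tris.append([ids[0], ids[k], ids[k + 1]])
    return np.array(verts, dtype=float), np.array(tris, dtype=np.int64)
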