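"""Element quality metrics for TET10 meshes.

Metrics (all normalized so the regular tetrahedron scores 1.0):

* aspect ratio: circumradius / (3 * inradius); 1.0 for the regular tet,
  growing without bound for slivers;
* corner Jacobian ratio: min over the 4 corners of
  det(e1, e2, e3) / (|e1| |e2| |e3|), normalized by the regular-tet value
  sqrt(2)/2; near 0 for degenerate corners;
* element size: mean length of the 6 vertex edges (mm).  This is the
  definition used everywhere a single per-element "size" is reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh

_REGULAR_CORNER = np.sqrt(2.0) / 2.0


@dataclass
class QualityReport:
    aspect_ratio: np.ndarray        # (E,)
    corner_jacobian: np.ndarray     # (E,) min corner Jacobian ratio
    size: np.ndarray                # (E,) mean vertex-edge length, mm
    edge_min: float = 0.0
    edge_max: float = 0.0
    edge_mean: float = 0.0
    edge_std: float = 0.0
    histograms: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_elements": int(self.size.size),
            "size_mean_mm": float(self.size.mean()),
            "size_std_mm": float(self.size.std()),
            "size_min_mm": float(self.size.min()),
            "size_max_mm": float(self.size.max()),
            "edge_min_mm": self.edge_min,
            "edge_max_mm": self.edge_max,
            "edge_mean_mm": self.edge_mean,
            "edge_std_mm": self.edge_std,
            "aspect_ratio_mean": float(self.aspect_ratio.mean()),
            "aspect_ratio_max": float(self.aspect_ratio.max()),
            "corner_jacobian_min": float(self.corner_jacobian.min()),
            "size_definition": self.metadata.get("size_definition", ""),
        }


def quality_report(mesh: Mesh, bins: int = 20) -> QualityReport:
    """Per-element quality metrics plus edge-length statistics.

    Degenerate elements are reported with quality 0 (aspect ratio inf is
    clipped to a large sentinel), never raised.
    """
    v = mesh.vertex_coords()  # (E, 4, 3)
    E = v.shape[0]

    # edge vectors / lengths
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edge_vecs = np.stack([v[:, j] - v[:, i] for i, j in pairs], axis=1)
    edge_len = np.linalg.norm(edge_vecs, axis=2)  # (E, 6)

    vol = np.abs(np.einsum("ei,ei->e",
                           np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                           v[:, 3] - v[:, 0])) / 6.0

    # face areas (for inradius r = 3V / sum(A))
    faces = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    areas = np.stack(
        [0.5 * np.linalg.norm(np.cross(v[:, b] - v[:, a], v[:, c] - v[:, a]), axis=1)
         for a, b, c in faces], axis=1)
    area_sum = areas.sum(axis=1)

    # circumradius: R = |a| |b| |c| ... use the standard formula
    # R = sqrt((p*q*r_)*(...)) / (24 V) with opposite-edge products
    aa = edge_len[:, 0] * edge_len[:, 5]   # |01| * |23|
    bb = edge_len[:, 1] * edge_len[:, 4]   # |02| * |13|
    cc = edge_len[:, 2] * edge_len[:, 3]   # |03| * |12|
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = np.sqrt(np.maximum(
            (aa + bb + cc) * (-aa + bb + cc) * (aa - bb + cc) * (aa + bb - cc),
            0.0)) / (24.0 * vol)
        inr = 3.0 * vol / area_sum
        aspect = circ / (3.0 * inr)
    aspect = np.where(np.isfinite(aspect), aspect, 1e9)
    aspect = np.where(vol > 0, aspect, 1e9)

    # corner Jacobian ratio
    corner = np.full(E, np.inf)
    for c in range(4):
        others = [o for o in range(4) if o != c]
        e1 = v[:, others[0]] - v[:, c]
        e2 = v[:, others[1]] - v[:, c]
        e3 = v[:, others[2]] - v[:, c]
        det = np.abs(np.einsum("ei,ei->e", np.cross(e1, e2), e3))
        prod = (np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
                * np.linalg.norm(e3, axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = det / prod / _REGULAR_CORNER
        corner = np.minimum(corner, np.where(np.isfinite(r), r, 0.0))

    size = edge_len.mean(axis=1)
    hists = {}
    for name, data in (("aspect_ratio", np.clip(aspect, 0, 10)),
                       ("corner_jacobian", corner),
                       ("size", size)):
        counts, edges = np.histogram(data, bins=bins)
        hists[name] = {"counts": counts, "bin_edges": edges}

    return QualityReport(
        aspect_ratio=aspect,
        corner_jacobian=corner,
        size=size,
        edge_min=float(edge_len.min()),
        edge_max=float(edge_len.max()),
        edge_mean=float(edge_len.mean()),
        edge_std=float(edge_len.std()),
        histograms=hists,
        metadata={"size_definition":
                  "mean length of the 6 vertex edges of each tetrahedron"},
    )
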