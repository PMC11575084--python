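"""Signed surface-to-surface distance fields and their summaries.

For a registered scan pair, every vertex of the later ("compared") scan is
matched to its nearest point on the earlier ("reference") surface. The
distance is signed by the reference's outward normal at the foot point:
positive means the compared surface lies outside the reference (swelling
excess), negative means a deficit. Exports follow the red=excess /
blue=deficit convention on a symmetric diverging colormap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapabilityError, EmptyRoiError, InvalidMeshError
from .mesh_io import (DISPLACEMENT_ATTR, SIGNED_DISTANCE_ATTR, TriangleMesh,
                      write_mesh)
from ._formats import write_vtk_polydata
from .roi import RoiSpec
from .spatial import SurfaceIndex
from .volumetry import signed_volume


@dataclass
class DistanceField:
    """Per-vertex signed distances (mm) of ``base`` against a reference scan."""

    base: TriangleMesh
    signed_distance: np.ndarray      # (n,) mm
    displacement: np.ndarray         # (n, 3) mm, base vertex minus foot point
    pair_label: str = ""

    def magnitudes(self) -> np.ndarray:
        return np.abs(self.signed_distance)


def _face_normals(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.vertices[mesh.faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    length = np.linalg.norm(n, axis=1, keepdims=True)
    length[length == 0] = 1.0
    return n / length


def signed_distance_field(compared: TriangleMesh, reference: TriangleMesh,
                          pair_label: str = "") -> DistanceField:
    """Signed closest-point distances from each ``compared`` vertex to the
    ``reference`` surface.

    Outward orientation of the reference is taken from its winding,
    globally normalized: if the reference is closed with a negative signed
    volume, its normals are flipped for the sign test.
    """
    if reference.n_faces == 0 or reference.n_vertices == 0:
        raise InvalidMeshError("reference mesh is empty")
    if compared.n_vertices == 0:
        raise InvalidMeshError("compared mesh is empty")
    index = SurfaceIndex(reference.vertices, reference.faces)
    feet, dist, face_idx = index.query(compared.vertices)
    disp = compared.vertices - feet
    normals = _face_normals(reference)
    flip = -1.0 if signed_volume(reference) < 0 else 1.0
    side = np.sign(np.einsum("ij,ij->i", disp, flip * normals[face_idx]))
    side[dist == 0] = 0.0
    signed = side * dist
    # zero-distance vertices have a zero displacement by construction
    return DistanceField(base=compared, signed_distance=signed,
                         displacement=disp, pair_label=pair_label)


def mean_linear_difference(field: DistanceField, roi: RoiSpec | None = None,
                           area_weighted: bool = False) -> float:
    """Mean signed distance (mm) over base-mesh vertices inside the ROI.

    The default is the vertex-uniform arithmetic mean; ``area_weighted``
    weights each vertex by one third of its incident triangle area.
    """
    inside = (roi.contains(field.base.vertices) if roi is not None
              else np.ones(len(field.signed_distance), dtype=bool))
    if not inside.any():
        raise EmptyRoiError("no vertices inside the region of interest")
    if not area_weighted:
        return float(field.signed_distance[inside].mean())
    tri = field.base.vertices[field.base.faces]
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0],
                                          tri[:, 2] - tri[:, 0]), axis=1)
    w = np.zeros(field.base.n_vertices)
    np.add.at(w, field.base.faces.reshape(-1), np.repeat(areas / 3.0, 3))
    w = w * inside
    if w.sum() == 0:
        raise EmptyRoiError("ROI vertices carry zero incident area")
    return float(np.sum(field.signed_distance * w) / w.sum())


def std_linear_difference(field: DistanceField, roi: RoiSpec | None = None) -> float:
    """Sample standard deviation of the signed distance over ROI vertices."""
    inside = (roi.contains(field.base.vertices) if roi is not None
              else np.ones(len(field.signed_distance), dtype=bool))
    if not inside.any():
        raise EmptyRoiError("no vertices inside the region of interest")
    vals = field.signed_distance[inside]
    return float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def diverging_colors(values: np.ndarray, span: float) -> np.ndarray:
    """Symmetric blue-white-red map: -span -> blue, 0 -> white, +span -> red,
    clamped outside. Returns (n, 3) uint8."""
    if span <= 0:
        raise ValueError("colormap span must be > 0")
    t = np.clip(np.asarray(values, dtype=np.float64) / span, -1.0, 1.0)
    rgb = np.empty((len(t), 3))
    neg = t < 0
    rgb[neg, 0] = rgb[neg, 1] = 255.0 * (1.0 + t[neg])
    rgb[neg, 2] = 255.0
    rgb[~neg, 0] = 255.0
    rgb[~neg, 1] = rgb[~neg, 2] = 255.0 * (1.0 - t[~neg])
    return np.rint(rgb).astype(np.uint8)


def default_span(field: DistanceField) -> float:
    """95th percentile of |signed distance|, with a 1 mm floor for flat fields."""
    p = float(np.percentile(np.abs(field.signed_distance), 95))
    return p if p > 1e-6 else 1.0


def colormap_export(field: DistanceField, path, span: float | None = None,
                    fmt: str = "auto") -> None:
    """Write the base mesh with signed distances and diverging vertex colors."""
    from pathlib import Path
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "stl":
        raise CapabilityError("STL cannot carry colors or distance attributes")
    if fmt not in ("ply", "vtk"):
        raise CapabilityError(f"unsupported colormap format '{fmt}'")
    if span is None:
        span = default_span(field)
    out = field.base.copy()
    out.vertex_scalars[SIGNED_DISTANCE_ATTR] = np.asarray(field.signed_distance,
                                                          dtype=np.float64)
    out.vertex_vectors[DISPLACEMENT_ATTR] = np.asarray(field.displacement,
                                                       dtype=np.float64)
    out.vertex_colors = diverging_colors(field.signed_distance, span)
    write_mesh(out, path, fmt)


def displacement_vector_export(field: DistanceField, path, stride: int = 1) -> None:
    """Write every stride-th vertex with its displacement vector as a VTK
    polydata point set, ready for glyph rendering."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    points = field.base.vertices[::stride]
    vectors = np.asarray(field.displacement, dtype=np.float64)[::stride]
    scalars = np.asarray(field.signed_distance, dtype=np.float64)[::stride]
    write_vtk_polydata(path, points, np.zeros((0, 3), dtype=np.int64),
                       {SIGNED_DISTANCE_ATTR: scalars},
                       {DISPLACEMENT_ATTR: vectors},
                       None, {"pair": field.pair_label} if field.pair_label else {},
                       as_vertices=True)
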