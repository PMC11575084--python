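"""Triangle-mesh container, readers/writers and structural diagnostics.

The pipeline's universal currency is :class:`TriangleMesh`: an indexed triangle
surface in millimetres with optional named per-vertex scalar and vector
attributes (signed distances, displacement vectors), optional 8-bit vertex
colors and a free-form metadata block. STL (ASCII + binary), PLY (ASCII +
binary_little_endian) and legacy VTK polydata ASCII are supported on disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import _formats
from .errors import (CapabilityError, InvalidMeshError, MeshFormatError,
                     UnsupportedTopologyError)

SIGNED_DISTANCE_ATTR = "signed_distance_mm"
DISPLACEMENT_ATTR = "displacement_mm"

_RESERVED_PLY_PROPS = {"x", "y", "z", "red", "green", "blue", "alpha",
                       "nx", "ny", "nz", "s", "t"}


@dataclass
class TriangleMesh:
    """Indexed triangle surface in mm with optional per-vertex attributes."""

    vertices: np.ndarray                      # (n, 3) float64, mm
    faces: np.ndarray                         # (m, 3) int64
    vertex_scalars: dict = field(default_factory=dict)   # name -> (n,) float64
    vertex_vectors: dict = field(default_factory=dict)   # name -> (n, 3) float64
    vertex_colors: np.ndarray | None = None   # (n, 3) uint8 or None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- basic properties ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """Axis-aligned bounding box as a (2, 3) [min; max] array, mm."""
        if self.n_vertices == 0:
            return np.zeros((2, 3))
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            vertex_scalars={k: np.array(v) for k, v in self.vertex_scalars.items()},
            vertex_vectors={k: np.array(v) for k, v in self.vertex_vectors.items()},
            vertex_colors=None if self.vertex_colors is None else self.vertex_colors.copy(),
            metadata=dict(self.metadata),
        )

    def validate(self) -> None:
        """Raise InvalidMeshError on any violated structural invariant."""
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidMeshError("vertices must be (n, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidMeshError("vertex coordinates contain NaN/Inf")
        if self.n_faces:
            if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
                raise InvalidMeshError("face index out of range")
            if np.any((self.faces[:, 0] == self.faces[:, 1])
                      | (self.faces[:, 1] == self.faces[:, 2])
                      | (self.faces[:, 0] == self.faces[:, 2])):
                raise InvalidMeshError("face with repeated vertex index")
        for name, arr in self.vertex_scalars.items():
            if len(arr) != self.n_vertices:
                raise InvalidMeshError(f"scalar '{name}' length != n_vertices")
        for name, arr in self.vertex_vectors.items():
            if np.shape(arr) != (self.n_vertices, 3):
                raise InvalidMeshError(f"vector '{name}' shape != (n_vertices, 3)")
        if self.vertex_colors is not None and len(self.vertex_colors) != self.n_vertices:
            raise InvalidMeshError("vertex_colors length != n_vertices")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class MeshDiagnostics:
    n_vertices: int
    n_faces: int
    n_boundary_loops: int
    is_watertight: bool
    is_consistently_oriented: bool
    bbox: np.ndarray

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bbox"] = np.asarray(self.bbox).tolist()
        return d


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def detect_format(path) -> str:
    """Detect mesh format from magic bytes, falling back to the extension."""
    path = Path(path)
    head = b""
    try:
        head = path.open("rb").read(256)
    except OSError as exc:
        raise MeshFormatError(f"{path}: cannot read file: {exc}") from exc
    if head.startswith(b"ply"):
        return "ply"
    if head.startswith(b"# vtk"):
        return "vtk"
    ext = path.suffix.lower().lstrip(".")
    if ext in ("stl", "ply", "vtk"):
        return "stl" if ext == "stl" else ext
    if head[:5].lower() == b"solid" or len(head) >= 84:
        return "stl"
    raise MeshFormatError(f"{path}: cannot detect mesh format from content or extension")


def read_mesh(path, fmt: str = "auto") -> TriangleMesh:
    """Read an STL/PLY/VTK-polydata surface into a TriangleMesh.

    STL facet corners that are bitwise-identical are merged into shared
    vertices (no epsilon welding); degenerate facets left with repeated
    indices after merging are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"{path}: file does not exist")
    if fmt == "auto":
        fmt = detect_format(path)
    if fmt == "vtk":
        v, f, sc, vec, col, meta = _formats.read_vtk_polydata(path)
        mesh = TriangleMesh(v, f, sc, vec, col, meta)
    elif fmt == "stl":
        mesh = _read_stl(path)
    elif fmt == "ply":
        mesh = _read_ply(path)
    else:
        raise MeshFormatError(f"{path}: unknown format '{fmt}'")
    mesh.validate()
    return mesh


def _load_trimesh(path, file_type):
    try:
        loaded = trimesh.load(str(path), file_type=file_type, process=False)
    except Exception as exc:  # noqa: BLE001 - normalize any parser failure
        raise MeshFormatError(f"{path}: failed to parse as {file_type}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh):
        raise UnsupportedTopologyError(f"{path}: file does not contain a triangle mesh")
    return loaded

def _read_stl(path) -> TriangleMesh:
    tm = _load_trimesh(path, "stl")
    raw_v = np.asarray(tm.vertices, dtype=np.float64)
    raw_f = np.asarray(tm.faces, dtype=np.int64)
    # exact (bitwise) merge of duplicated facet corners
    uniq, inverse = np.unique(raw_v, axis=0, return_inverse=True)
    faces = inverse[raw_f]
    good = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2]))
    meta = {}
    header = tm.metadata.get("header")
    if header:
        meta["header"] = str(header)
    return TriangleMesh(uniq, faces[good], metadata=meta)


def _read_ply(path) -> TriangleMesh:
    tm = _load_trimesh(path, "ply")
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    scalars, vectors = {}, {}
    raw = tm.metadata.get("_ply_raw", {})
    vdata = raw.get("vertex", {}).get("data")
    fdata = raw.get("face", {}).get("data")
    if fdata is not None and "vertex_indices" in _keys(fdata):
        _check_triangular(fdata["vertex_indices"], path)
    if vdata is not None:
        names = _keys(vdata)
        pending = {}
        for name in names:
            if name in _RESERVED_PLY_PROPS:
                continue
            arr = np.asarray(vdata[name] if isinstance(vdata, dict) else vdata[name])
            if arr.ndim == 2 and arr.shape[1] == 3:
                vectors[name] = arr.astype(np.float64)
            elif name.endswith(("_x", "_y", "_z")):
                pending.setdefault(name[:-2], {})[name[-1]] = arr.astype(np.float64)
            else:
                scalars[name] = arr.astype(np.float64).reshape(-1)
        for base, comps in pending.items():
            if set(comps) == {"x", "y", "z"}:
                vectors[base] = np.column_stack([comps["x"], comps["y"], comps["z"]])
            else:  # incomplete triple: keep components as plain scalars
                for suffix, arr in comps.items():
                    scalars[f"{base}_{suffix}"] = arr.reshape(-1)
    colors = None
    if tm.visual is not None and getattr(tm.visual, "kind", None) == "vertex":
        colors = np.asarray(tm.visual.vertex_colors[:, :3], dtype=np.uint8)
    meta = {}
    for key, value in tm.metadata.items():
        if isinstance(value, str):
            meta[key] = value
    return TriangleMesh(vertices, faces, scalars, vectors, colors, meta)


def _keys(data):
    if isinstance(data, dict):
        return list(data.keys())
    return list(data.dtype.names or [])


def _check_triangular(idx, path):
    """Raise on polygonal PLY faces (only triangles are supported)."""
    if isinstance(idx, np.ndarray):
        if idx.dtype.names:  # binary list property: (count, (k,) indices)
            sub = idx.dtype[idx.dtype.names[-1]]
            if sub.shape and sub.shape[0] != 3:
                raise UnsupportedTopologyError(
                    f"{path}: non-triangular faces with {sub.shape[0]} vertices")
            return
        if idx.ndim == 2:
            if idx.shape[1] != 3:
                raise UnsupportedTopologyError(
                    f"{path}: non-triangular faces with {idx.shape[1]} vertices")
            return
    for row in list(idx):
        if hasattr(row, "__len__") and len(row) != 3:
            raise UnsupportedTopologyError(
                f"{path}: non-triangular face with {len(row)} vertices")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_mesh(mesh: TriangleMesh, path, fmt: str = "auto", *, binary: bool = False,
               drop_attributes: bool = False) -> None:
    """Write a TriangleMesh to STL/PLY/VTK-polydata.

    STL cannot carry attributes or colors; writing an attributed mesh as STL
    raises CapabilityError unless ``drop_attributes`` is set.
    """
    mesh.validate()
    path = Path(path)
    if fmt == "auto":
        ext = path.suffix.lower().lstrip(".")
        if ext not in ("stl", "ply", "vtk"):
            raise CapabilityError(f"{path}: cannot infer format from extension '{ext}'")
        fmt = ext
    if fmt == "stl":
        has_attrs = (mesh.vertex_scalars or mesh.vertex_vectors
                     or mesh.vertex_colors is not None)
        if has_attrs and not drop_attributes:
            raise CapabilityError(
                "STL carries no per-vertex attributes; pass drop_attributes=True "
                "to write geometry only")
        tm = mesh.to_trimesh()
        if binary:
            path.write_bytes(trimesh.exchange.stl.export_stl(tm))
        else:
            path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
    elif fmt == "ply":
        _formats.write_ply(path, mesh.vertices, mesh.faces, mesh.vertex_scalars,
                           mesh.vertex_vectors, mesh.vertex_colors, mesh.metadata,
                           binary=binary)
    elif fmt == "vtk":
        _formats.write_vtk_polydata(path, mesh.vertices, mesh.faces,
                                    mesh.vertex_scalars, mesh.vertex_vectors,
                                    mesh.vertex_colors, mesh.metadata)
    else:
        raise CapabilityError(f"unknown format '{fmt}'")


# ---------------------------------------------------------------------------
# Anonymization & diagnostics
# ---------------------------------------------------------------------------

def anonymize(mesh: TriangleMesh) -> TriangleMesh:
    """Strip identifying content: metadata block and color/texture attributes.

    Geometry (vertices, faces) and measurement attributes are untouched.
    """
    out = mesh.copy()
    out.metadata = {}
    out.vertex_colors = None
    return out


def _edge_tables(faces):
    directed = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    return directed, undirected


def diagnose(mesh: TriangleMesh) -> MeshDiagnostics:
    """Structural diagnostics: boundary loops, watertightness, orientation."""
    mesh.validate()
    if mesh.n_faces == 0:
        return MeshDiagnostics(mesh.n_vertices, 0, 0, False, True, mesh.bounds)
    directed, undirected = _edge_tables(mesh.faces)
    _, inverse, counts = np.unique(undirected, axis=0, return_inverse=True,
                                   return_counts=True)
    edge_counts = counts[inverse]          # per directed-edge occurrence
    boundary_mask = edge_counts == 1
    watertight = bool(np.all(counts == 2))
    # consistent orientation: no directed edge appears twice
    _, dcounts = np.unique(directed, axis=0, return_counts=True)
    consistent = bool(np.all(dcounts == 1))
    n_loops = _count_boundary_loops(directed[boundary_mask])
    return MeshDiagnostics(mesh.n_vertices, mesh.n_faces, n_loops,
                           watertight and n_loops == 0, consistent, mesh.bounds)


def boundary_loops(mesh: TriangleMesh) -> list[np.ndarray]:
    """Ordered vertex cycles of each boundary loop (directed as in the faces)."""
    directed, undirected = _edge_tables(mesh.faces)
    _, inverse, counts = np.unique(undirected, axis=0, return_inverse=True,
                                   return_counts=True)
    return _trace_loops(directed[counts[inverse] == 1])


def _trace_loops(boundary_edges) -> list[np.ndarray]:
    """Decompose directed boundary edges into simple vertex cycles.

    Boundary edge sets have equal in/out degree at every vertex, so they split
    into edge-disjoint cycles; a cycle is emitted whenever the walk revisits a
    vertex on the current path, which keeps every emitted loop simple even at
    pinch vertices shared by two holes.
    """
    succ: dict[int, list[int]] = {}
    for a, b in boundary_edges:
        succ.setdefault(int(a), []).append(int(b))
    for v in succ:
        succ[v].sort(reverse=True)        # pop() then takes the smallest
    loops = []
    for start in sorted(succ):
        while succ[start]:
            path = [start]
            pos = {start: 0}
            cur = start
            while succ.get(cur):
                nxt = succ[cur].pop()
                if nxt in pos:
                    cycle = path[pos[nxt]:]
                    if len(cycle) >= 3:
                        loops.append(np.array(cycle, dtype=np.int64))
                    for v in cycle[1:]:
                        pos.pop(v, None)
                    del path[pos[nxt] + 1:]
                    cur = nxt
                else:
                    path.append(nxt)
                    pos[nxt] = len(path) - 1
                    cur = nxt
    return loops


def _count_boundary_loops(boundary_edges) -> int:
    return len(_trace_loops(boundary_edges))
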