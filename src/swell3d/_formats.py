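"""Low-level writers/readers for surface formats the pipeline exchanges.

PLY writing is done here with float64 ("double") properties so that geometry and
per-vertex measurements round-trip at full precision; legacy VTK polydata ASCII is
read and written here as well. Reading of STL/PLY goes through trimesh (mesh_io).
"""

from __future__ import annotations

import json
import struct

import numpy as np

from .errors import MeshFormatError, UnsupportedTopologyError

_F = "%.17g"  # shortest lossless-ish decimal for float64


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

def write_ply(path, vertices, faces, scalars, vectors, colors, metadata, binary):
    """Write a PLY file (ASCII or binary_little_endian) with optional per-vertex
    uchar colors, double scalar properties and double vector properties encoded
    as ``<name>_x/_y/_z`` triples."""
    n, m = len(vertices), len(faces)
    lines = ["ply"]
    lines.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    for key, value in (metadata or {}).items():
        lines.append(f"comment {key}: {value}")
    lines.append(f"element vertex {n}")
    lines += ["property double x", "property double y", "property double z"]
    if colors is not None:
        lines += ["property uchar red", "property uchar green", "property uchar blue"]
    for name in scalars:
        lines.append(f"property double {name}")
    for name in vectors:
        for suffix in ("x", "y", "z"):
            lines.append(f"property double {name}_{suffix}")
    lines.append(f"element face {m}")
    lines.append("property list uchar int32 vertex_indices")
    lines.append("end_header")
    header = ("\n".join(lines) + "\n").encode("ascii")

    cols = [np.asarray(vertices, dtype=np.float64)]
    fmts = ["d", "d", "d"]
    if colors is not None:
        cols.append(np.asarray(colors[:, :3], dtype=np.uint8))
        fmts += ["B", "B", "B"]
    for name in scalars:
        cols.append(np.asarray(scalars[name], dtype=np.float64).reshape(n, 1))
        fmts.append("d")
    for name in vectors:
        cols.append(np.asarray(vectors[name], dtype=np.float64))
        fmts += ["d", "d", "d"]

    with open(path, "wb") as fh:
        fh.write(header)
        if binary:
            dtype = np.dtype([(f"f{i}", "<" + f) for i, f in enumerate(_flat_formats(fmts))])
            rec = np.empty(n, dtype=dtype)
            i = 0
            for col in cols:
                col2 = np.atleast_2d(col.T).T
                for j in range(col2.shape[1]):
                    rec[f"f{i}"] = col2[:, j]
                    i += 1
            fh.write(rec.tobytes())
            fdt = np.dtype([("c", "u1"), ("idx", "<i4", (3,))])
            frec = np.empty(m, dtype=fdt)
            frec["c"] = 3
            frec["idx"] = np.asarray(faces, dtype=np.int32)
            fh.write(frec.tobytes())
        else:
            for i in range(n):
                parts = []
                for col in cols:
                    row = np.atleast_1d(col[i])
                    for v in row:
                        parts.append(str(int(v)) if row.dtype == np.uint8 else _F % v)
                fh.write((" ".join(parts) + "\n").encode("ascii"))
            for f in np.asarray(faces, dtype=np.int64):
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


def _flat_formats(fmts):
    return list(fmts)


# ---------------------------------------------------------------------------
# Legacy VTK polydata (ASCII)
# ---------------------------------------------------------------------------

def write_vtk_polydata(path, vertices, faces, scalars, vectors, colors, metadata,
                       as_vertices=False):
    """Write legacy VTK ASCII polydata. ``as_vertices=True`` emits VERTICES cells
    (a glyph-ready point set) instead of POLYGONS."""
    n = len(vertices)
    title = json.dumps(metadata, sort_keys=True) if metadata else "swell3d polydata"
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p in np.asarray(vertices, dtype=np.float64):
            fh.write(f"{_F % p[0]} {_F % p[1]} {_F % p[2]}\n")
        if as_vertices:
            fh.write(f"VERTICES {n} {2 * n}\n")
            for i in range(n):
                fh.write(f"1 {i}\n")
        else:
            m = len(faces)
            fh.write(f"POLYGONS {m} {4 * m}\n")
            for f in np.asarray(faces, dtype=np.int64):
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if scalars or vectors or colors is not None:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in (scalars or {}).items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr, dtype=np.float64):
                    fh.write(f"{_F % v}\n")
            for name, arr in (vectors or {}).items():
                fh.write(f"VECTORS {name} double\n")
                for v in np.asarray(arr, dtype=np.float64):
                    fh.write(f"{_F % v[0]} {_F % v[1]} {_F % v[2]}\n")
            if colors is not None:
                fh.write(f"COLOR_SCALARS rgb 3\n")
                for c in np.asarray(colors[:, :3], dtype=np.float64) / 255.0:
                    fh.write(f"{_F % c[0]} {_F % c[1]} {_F % c[2]}\n")


def read_vtk_polydata(path):
    """Parse legacy VTK ASCII polydata with triangular POLYGONS.

    Returns (vertices, faces, scalars, vectors, colors, metadata).
    Raises MeshFormatError with the offending line number on malformed input.
    """
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        lines = fh.read().splitlines()

    def err(lineno, msg):
        raise MeshFormatError(f"{path}: line {lineno + 1}: {msg}")

    if not lines or not lines[0].startswith("# vtk DataFile"):
        err(0, "missing '# vtk DataFile' header")
    title = lines[1] if len(lines) > 1 else ""
    metadata = {}
    try:
        parsed = json.loads(title)
        if isinstance(parsed, dict):
            metadata = parsed
    except (json.JSONDecodeError, IndexError):
        pass
    if len(lines) < 4 or lines[2].strip().upper() != "ASCII":
        err(2, "only ASCII legacy VTK files are supported")
    if lines[3].strip().upper() != "DATASET POLYDATA":
        err(3, "expected 'DATASET POLYDATA'")

    # tokenize the remainder, keeping track of line numbers per token
    tokens, tok_line = [], []
    for ln in range(4, len(lines)):
        for t in lines[ln].split():
            tokens.append(t)
            tok_line.append(ln)
    pos = 0

    def take(count, cast, what):
        nonlocal pos
        if pos + count > len(tokens):
            err(tok_line[-1] if tokens else 4, f"unexpected end of file reading {what}")
        try:
            out = [cast(t) for t in tokens[pos:pos + count]]
        except ValueError:
            err(tok_line[pos], f"bad value while reading {what}")
        pos += count
        return out

    vertices = faces = None
    scalars, vectors, colors = {}, {}, None
    while pos < len(tokens):
        kw = tokens[pos].upper()
        lineno = tok_line[pos]
        pos += 1
        if kw == "POINTS":
            n = int(take(1, int, "POINTS count")[0])
            take(1, str, "POINTS dtype")
            vals = take(3 * n, float, "POINTS coordinates")
            vertices = np.array(vals, dtype=np.float64).reshape(n, 3)
        elif kw == "POLYGONS":
            m = int(take(1, int, "POLYGONS count")[0])
            size = int(take(1, int, "POLYGONS size")[0])
            vals = take(size, int, "POLYGONS connectivity")
            faces, i = [], 0
            for _ in range(m):
                k = vals[i]
                if k != 3:
                    raise UnsupportedTopologyError(
                        f"{path}: line {lineno + 1}: non-triangular polygon with {k} vertices")
                faces.append(vals[i + 1:i + 4])
                i += k + 1
            faces = np.array(faces, dtype=np.int64).reshape(-1, 3)
        elif kw == "VERTICES":
            m = int(take(1, int, "VERTICES count")[0])
            size = int(take(1, int, "VERTICES size")[0])
            take(size, int, "VERTICES connectivity")
            faces = np.zeros((0, 3), dtype=np.int64)
        elif kw == "POINT_DATA":
            take(1, int, "POINT_DATA count")
        elif kw == "SCALARS":
            name, _dtype = take(2, str, "SCALARS header")
            ncomp = 1
            if pos < len(tokens) and tokens[pos].isdigit():
                ncomp = int(take(1, int, "SCALARS components")[0])
            if pos < len(tokens) and tokens[pos].upper() == "LOOKUP_TABLE":
                take(2, str, "LOOKUP_TABLE")
            vals = take(ncomp * len(vertices), float, f"SCALARS {name}")
            arr = np.array(vals, dtype=np.float64).reshape(len(vertices), ncomp)
            scalars[name] = arr[:, 0] if ncomp == 1 else arr
        elif kw == "VECTORS":
            name, _dtype = take(2, str, "VECTORS header")
            vals = take(3 * len(vertices), float, f"VECTORS {name}")
            vectors[name] = np.array(vals, dtype=np.float64).reshape(len(vertices), 3)
        elif kw == "COLOR_SCALARS":
            name = take(1, str, "COLOR_SCALARS name")[0]
            ncomp = int(take(1, int, "COLOR_SCALARS components")[0])
            vals = take(ncomp * len(vertices), float, f"COLOR_SCALARS {name}")
            arr = np.array(vals, dtype=np.float64).reshape(len(vertices), ncomp)
            colors = np.rint(arr[:, :3] * 255.0).astype(np.uint8)
        else:
            err(lineno, f"unrecognized keyword '{kw}'")
    if vertices is None:
        err(4, "no POINTS section found")
    if faces is None:
        faces = np.zeros((0, 3), dtype=np.int64)
    return vertices, faces, scalars, vectors, colors, metadata
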