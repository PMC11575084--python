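"""Mesh I/O: format round-trips, STL corner merging, anonymization, diagnostics."""

import numpy as np
import pytest

from swell3d import (TriangleMesh, anonymize, close_mesh, diagnose, read_mesh,
                     write_mesh)
from swell3d.errors import (CapabilityError, MeshFormatError,
                            UnsupportedTopologyError)

def _cube_stl_text():
    import trimesh
    box = trimesh.creation.box(extents=(1, 1, 1))
    return trimesh.exchange.stl.export_stl_ascii(box)


def test_ascii_stl_cube_merges_to_shared_vertices(tmp_path):
    path = tmp_path / "cube.stl"
    path.write_text(_cube_stl_text())
    mesh = read_mesh(path)
    assert mesh.n_vertices == 8
    assert mesh.n_faces == 12
    assert diagnose(mesh).is_watertight


def test_binary_stl_icosphere_counts(tmp_path, ico3):
    path = tmp_path / "ico.stl"
    write_mesh(ico3, path, "stl", binary=True)
    mesh = read_mesh(path)
    assert mesh.n_vertices == 642      # 10 * 4**3 + 2
    assert mesh.n_faces == 1280        # 20 * 4**3


@pytest.mark.parametrize("fmt,binary", [("ply", False), ("ply", True),
                                        ("vtk", False)])
def test_attribute_roundtrip_full_precision(tmp_path, ico3, fmt, binary):
    mesh = ico3.copy()
    rng = np.random.default_rng(7)
    mesh.vertex_scalars["signed_distance_mm"] = rng.normal(size=mesh.n_vertices)
    mesh.vertex_vectors["displacement_mm"] = rng.normal(size=(mesh.n_vertices, 3))
    path = tmp_path / f"mesh.{fmt}"
    write_mesh(mesh, path, fmt, binary=binary)
    back = read_mesh(path)
    np.testing.assert_array_equal(back.vertices, mesh.vertices)
    np.testing.assert_array_equal(back.faces, mesh.faces)
    np.testing.assert_array_equal(back.vertex_scalars["signed_distance_mm"],
                                  mesh.vertex_scalars["signed_distance_mm"])
    np.testing.assert_array_equal(back.vertex_vectors["displacement_mm"],
                                  mesh.vertex_vectors["displacement_mm"])


def test_stl_roundtrip_geometry(tmp_path, ico3):
    path = tmp_path / "geo.stl"
    write_mesh(ico3, path, "stl", binary=True)
    back = read_mesh(path)
    # binary STL stores float32: equality up to storage precision and reindexing
    assert back.n_vertices == ico3.n_vertices
    a = np.sort(back.vertices.round(4).view([("x", float), ("y", float), ("z", float)]),
                order=["x", "y", "z"], axis=0)
    b = np.sort(ico3.vertices.round(4).view([("x", float), ("y", float), ("z", float)]),
                order=["x", "y", "z"], axis=0)
    np.testing.assert_allclose(
        a.view(float).reshape(-1, 3), b.view(float).reshape(-1, 3), atol=2e-4)


def test_stl_refuses_attributes_without_drop_flag(tmp_path, ico3):
    mesh = ico3.copy()
    mesh.vertex_scalars["signed_distance_mm"] = np.zeros(mesh.n_vertices)
    with pytest.raises(CapabilityError):
        write_mesh(mesh, tmp_path / "x.stl", "stl")
    write_mesh(mesh, tmp_path / "x.stl", "stl", drop_attributes=True)
    assert read_mesh(tmp_path / "x.stl").vertex_scalars == {}


def test_read_errors_name_the_problem(tmp_path):
    bad = tmp_path / "bad.vtk"
    bad.write_text("# vtk DataFile Version 3.0\ntitle\nASCII\nDATASET POLYDATA\n"
                   "POINTS 2 double\n0 0 0\n1 1 oops\n")
    with pytest.raises(MeshFormatError, match="line"):
        read_mesh(bad)
    missing = tmp_path / "nope.ply"
    with pytest.raises(MeshFormatError, match="does not exist"):
        read_mesh(missing)


def test_vtk_non_triangular_polygon_rejected(tmp_path):
    quad = tmp_path / "quad.vtk"
    quad.write_text("# vtk DataFile Version 3.0\nq\nASCII\nDATASET POLYDATA\n"
                    "POINTS 4 double\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n"
                    "POLYGONS 1 5\n4 0 1 2 3\n")
    with pytest.raises(UnsupportedTopologyError):
        read_mesh(quad)


def test_anonymize_strips_identity_not_geometry(ico3):
    mesh = ico3.copy()
    mesh.metadata = {"patient": "X", "scanner": "app 2.5.2"}
    mesh.vertex_colors = np.full((mesh.n_vertices, 3), 128, dtype=np.uint8)
    clean = anonymize(mesh)
    assert clean.metadata == {}
    assert clean.vertex_colors is None
    np.testing.assert_array_equal(clean.vertices, mesh.vertices)
    np.testing.assert_array_equal(clean.faces, mesh.faces)
    # input untouched
    assert mesh.metadata["patient"] == "X"


def test_diagnose_boundary_loops(ico3):
    d = diagnose(ico3)
    assert d.is_watertight and d.n_boundary_loops == 0
    assert d.is_consistently_oriented

    # remove the faces around one vertex: a single hole
    keep = ~np.any(ico3.faces == 5, axis=1)
    holed = TriangleMesh(ico3.vertices, ico3.faces[keep])
    dh = diagnose(holed)
    assert dh.n_boundary_loops == 1
    assert not dh.is_watertight

    # open tube: two rims
    theta = np.linspace(0, 2 * np.pi, 17)[:-1]
    ring = np.column_stack([5 * np.cos(theta), 5 * np.sin(theta), np.zeros(16)])
    vertices = np.vstack([ring, ring + [0, 0, 10.0]])
    faces = []
    for k in range(16):
        a, b = k, (k + 1) % 16
        faces += [[a, b, 16 + b], [a, 16 + b, 16 + a]]
    dt = diagnose(TriangleMesh(vertices, np.array(faces, dtype=np.int64)))
    assert dt.n_boundary_loops == 2


def test_diagnose_invariant_under_reindexing(ico3):
    rng = np.random.default_rng(3)
    perm = rng.permutation(ico3.n_vertices)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    shuffled = TriangleMesh(ico3.vertices[perm], inv[ico3.faces])
    d0, d1 = diagnose(ico3), diagnose(shuffled)
    assert (d0.n_boundary_loops, d0.is_watertight) == (d1.n_boundary_loops,
                                                       d1.is_watertight)
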