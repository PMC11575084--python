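"""Signed distance fields, ROI means, colormap and vector exports."""

import numpy as np
import pytest

from oracles import brute_force_closest

from swell3d import (RoiSpec, TriangleMesh, mean_linear_difference, read_mesh,
                     signed_distance_field, std_linear_difference)
from swell3d.distances import (colormap_export, displacement_vector_export,
                               diverging_colors)
from swell3d.errors import CapabilityError, EmptyRoiError
from swell3d.spatial import SurfaceIndex
from swell3d.synthetic import random_rigid_transform
from swell3d.registration import apply_transform
from conftest import icosphere_mesh


def _sphere(radius, subdivisions=4):
    m = icosphere_mesh(subdivisions, 1.0)
    return TriangleMesh(m.vertices * radius, m.faces)


def test_surface_index_matches_brute_force(ico3):
    rng = np.random.default_rng(8)
    points = rng.uniform(-15, 15, size=(200, 3))
    index = SurfaceIndex(ico3.vertices, ico3.faces)
    feet, dist, _ = index.query(points)
    feet_bf, dist_bf = brute_force_closest(points, ico3.vertices, ico3.faces)
    np.testing.assert_allclose(dist, dist_bf, atol=1e-9)
    np.testing.assert_allclose(feet, feet_bf, atol=1e-7)


def test_zero_field_on_identical_meshes(ico3):
    field = signed_distance_field(ico3, ico3)
    np.testing.assert_allclose(field.signed_distance, 0.0, atol=1e-9)
    np.testing.assert_allclose(field.displacement, 0.0, atol=1e-9)


def test_concentric_spheres_give_radial_offset():
    inner, outer = _sphere(50.0), _sphere(51.0)
    field = signed_distance_field(outer, inner)
    assert np.all(np.abs(field.signed_distance - 1.0) < 0.01)
    swapped = signed_distance_field(inner, outer)
    assert np.all(np.abs(swapped.signed_distance + 1.0) < 0.01)
    # magnitude invariant: |signed| == ||displacement||
    np.testing.assert_allclose(np.abs(field.signed_distance),
                               np.linalg.norm(field.displacement, axis=1),
                               atol=1e-9)


def test_plane_below_reference_is_negative():
    grid = np.linspace(-10, 10, 9)
    gx, gy = np.meshgrid(grid, grid)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    n = len(grid)
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces += [[a, a + n, a + n + 1], [a, a + n + 1, a + 1]]
    faces = np.array(faces, dtype=np.int64)
    lower = TriangleMesh(pts, faces)
    upper = TriangleMesh(pts + [0, 0, 2.0], faces)
    field = signed_distance_field(lower, upper)
    interior = np.all(np.abs(lower.vertices[:, :2]) < 8, axis=1)
    np.testing.assert_allclose(field.signed_distance[interior], -2.0, atol=1e-9)


def test_field_invariant_under_common_rigid_motion(ico3, ico4):
    compared = TriangleMesh(ico4.vertices * 1.02, ico4.faces)
    f0 = signed_distance_field(compared, ico3)
    motion = random_rigid_transform(np.random.default_rng(1), 30.0, 20.0)
    f1 = signed_distance_field(apply_transform(compared, motion),
                               apply_transform(ico3, motion))
    np.testing.assert_allclose(f1.signed_distance, f0.signed_distance, atol=1e-6)


def test_mean_and_sd_over_roi():
    inner, outer = _sphere(50.0, 3), _sphere(51.0, 3)
    field = signed_distance_field(outer, inner)
    whole = mean_linear_difference(field)
    assert whole == pytest.approx(1.0, abs=0.01)
    assert std_linear_difference(field) < 0.01
    upper = RoiSpec([(np.zeros(3), np.array([0.0, 0.0, 1.0]))])
    assert mean_linear_difference(field, upper) == pytest.approx(1.0, abs=0.01)
    nothing = RoiSpec([(np.array([0.0, 0.0, 100.0]), np.array([0.0, 0.0, 1.0]))])
    with pytest.raises(EmptyRoiError):
        mean_linear_difference(field, nothing)


def test_mean_invariant_under_vertex_reindexing():
    inner, outer = _sphere(50.0, 3), _sphere(51.0, 3)
    field = signed_distance_field(outer, inner)
    rng = np.random.default_rng(6)
    perm = rng.permutation(outer.n_vertices)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    shuffled = TriangleMesh(outer.vertices[perm], inv[outer.faces])
    f2 = signed_distance_field(shuffled, inner)
    assert mean_linear_difference(f2) == pytest.approx(
        mean_linear_difference(field), abs=1e-12)


def test_diverging_colormap_endpoints():
    colors = diverging_colors(np.array([-4.0, -2.0, 0.0, 2.0, 1.0]), span=2.0)
    np.testing.assert_array_equal(colors[0], [0, 0, 255])      # clamped blue
    np.testing.assert_array_equal(colors[1], [0, 0, 255])      # -span: blue
    np.testing.assert_array_equal(colors[2], [255, 255, 255])  # 0: white
    np.testing.assert_array_equal(colors[3], [255, 0, 0])      # +span: red
    assert colors[4][0] == 255 and 0 < colors[4][1] < 255      # mid: pinkish


def test_colormap_export_roundtrip(tmp_path, ico3):
    compared = TriangleMesh(ico3.vertices * 1.1, ico3.faces)
    field = signed_distance_field(compared, ico3)
    out = tmp_path / "cmap.ply"
    colormap_export(field, out, span=2.0)
    back = read_mesh(out)
    assert "signed_distance_mm" in back.vertex_scalars
    assert "displacement_mm" in back.vertex_vectors
    assert back.vertex_colors is not None
    np.testing.assert_array_equal(back.vertex_scalars["signed_distance_mm"],
                                  field.signed_distance)
    with pytest.raises(CapabilityError):
        colormap_export(field, tmp_path / "cmap.stl", span=2.0)


def test_vector_export_stride_and_radial_direction(tmp_path):
    inner, outer = _sphere(50.0), _sphere(51.0)
    field = signed_distance_field(outer, inner)
    out = tmp_path / "vectors.vtk"
    displacement_vector_export(field, out, stride=4)
    from swell3d._formats import read_vtk_polydata
    v, f, scalars, vectors, _, _ = read_vtk_polydata(out)
    assert len(v) == int(np.ceil(outer.n_vertices / 4))
    disp = vectors["displacement_mm"]
    radial = v / np.linalg.norm(v, axis=1, keepdims=True)
    unit = disp / np.linalg.norm(disp, axis=1, keepdims=True)
    angles = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", radial, unit),
                                          -1, 1)))
    assert np.all(angles < 5.0)
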