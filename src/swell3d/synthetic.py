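"""Synthetic head-like fixtures with parametrically known swelling.

The generator emulates the study design — three surface scans of the same
face (pre-operative T0, post-operative T1 with swelling, follow-up T2 with
partial resolution) — on an ellipsoidal head whose added swelling volume is
known from the generator's own oracle, so every pipeline stage can be tested
against ground truth without any acquired data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .mesh_io import TriangleMesh, write_mesh
from .registration import LandmarkSet, RigidTransform
from .volumetry import mesh_volume

#: (p, q, r) ellipsoid parameters (x/a, y/b, z/c) of each synthetic landmark;
#: p^2 + q^2 + r^2 = 1 puts the point on the surface. The frame is canonical:
#: x toward the subject's left, y anterior, z superior, porion midpoint at 0.
_LANDMARK_PARAMS = {
    "porion_left": (1.0, 0.0, 0.0),
    "porion_right": (-1.0, 0.0, 0.0),
    "orbitale_left": (0.5, 0.8660254037844386, 0.0),
    "nasion": (0.0, 0.9847319278346618, 0.17408301076),
    "subnasale": (0.0, 0.995, -0.09987492177719089),
    "zygomatic_superior": (0.7493997598, 0.5620498199, 0.35),
    "submandibular_inferior": (0.18734994, 0.24979992, -0.95),
    "preauricular_posterior": (0.85, -0.35, 0.3937003937),
    "midline_anterior": (0.0, 1.0, 0.0),
}

#: default bump placement: left cheek, well inside the ROI boundaries
DEFAULT_BUMP_DIRECTION = (0.886, 0.344, -0.310)


def _ellipsoid_point(params, semi_axes) -> np.ndarray:
    u = np.asarray(params[:3], dtype=np.float64)
    u = u / np.linalg.norm(u)
    return u * np.asarray(semi_axes, dtype=np.float64)


def generate_head(semi_axes=(70.0, 90.0, 100.0), subdivision: int = 4
                  ) -> tuple[TriangleMesh, LandmarkSet]:
    """Watertight ellipsoidal head (subdivided icosahedron) with synthetic
    anatomical landmarks, generated directly in the canonical frame."""
    semi_axes = np.asarray(semi_axes, dtype=np.float64)
    if np.any(semi_axes <= 0):
        raise ValueError("semi-axes must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
    mesh = TriangleMesh(np.asarray(ico.vertices) * semi_axes,
                        np.asarray(ico.faces, dtype=np.int64))
    points = {name: _ellipsoid_point(p, semi_axes)
              for name, p in _LANDMARK_PARAMS.items()}
    return mesh, LandmarkSet(points, side="left")


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted outward vertex normals (unit length)."""
    tri = mesh.vertices[mesh.faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area-weighted
    vn = np.zeros_like(mesh.vertices)
    np.add.at(vn, mesh.faces.reshape(-1), np.repeat(fn, 3, axis=0).reshape(-1, 3))
    length = np.linalg.norm(vn, axis=1, keepdims=True)
    length[length == 0] = 1.0
    return vn / length


def add_swelling_bump(mesh: TriangleMesh, center, amplitude: float,
                      sigma: float) -> tuple[TriangleMesh, float]:
    """Displace vertices outward by a Gaussian bump; returns (mesh, added mm^3).

    Each vertex moves along the *base* mesh's area-weighted normal by
    ``amplitude * exp(-d^2 / (2 sigma^2))`` with d the Euclidean distance to
    ``center``. The added volume is measured by the generator's own oracle:
    the difference of enclosed volumes after vs before, at the generation
    resolution (meshes auto-closed if open).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    center = np.asarray(center, dtype=np.float64).reshape(3)
    out = mesh.copy()
    if amplitude == 0:
        return out, 0.0
    d2 = np.einsum("ij,ij->i", mesh.vertices - center, mesh.vertices - center)
    magnitude = amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
    out.vertices = mesh.vertices + magnitude[:, None] * vertex_normals(mesh)
    added = (mesh_volume(out, auto_close=True).volume
             - mesh_volume(mesh, auto_close=True).volume)
    return out, added


def make_slab(side: float = 100.0, thickness: float = 25.0,
              resolution: float = 1.0) -> TriangleMesh:
    """Closed thin slab whose top face is a finely gridded square at z = 0,
    centred on the origin — a flat stage for analytic bump-volume checks."""
    n = max(1, int(round(side / resolution)))
    xs = np.linspace(-side / 2.0, side / 2.0, n + 1)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    top = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    bottom = top + np.array([0.0, 0.0, -thickness])

    def vid(i, j):
        return i * (n + 1) + j

    faces_top = []
    for i in range(n):
        for j in range(n):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces_top += [[a, b, c], [a, c, d]]
    faces_top = np.array(faces_top, dtype=np.int64)
    # outward top winding: normal must be +z; grid above yields -z, so flip
    tri = top[faces_top]
    if np.cross(tri[0, 1] - tri[0, 0], tri[0, 2] - tri[0, 0])[2] < 0:
        faces_top = faces_top[:, ::-1]
    offset = len(top)
    faces_bottom = faces_top[:, ::-1] + offset
    # stitch the boundary ring
    ring = ([vid(0, j) for j in range(n)] + [vid(i, n) for i in range(n)]
            + [vid(n, j) for j in range(n, 0, -1)] + [vid(i, 0) for i in range(n, 0, -1)])
    side_faces = []
    for k in range(len(ring)):
        a, b = ring[k], ring[(k + 1) % len(ring)]
        side_faces += [[a, b, b + offset], [a, b + offset, a + offset]]
    vertices = np.vstack([top, bottom])
    faces = np.vstack([faces_top, faces_bottom, np.array(side_faces, dtype=np.int64)])
    mesh = TriangleMesh(vertices, faces)
    # normalize global winding to outward
    from .volumetry import signed_volume
    if signed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


@dataclass
class SwellingScenario:
    """Parameters of one synthetic T0/T1/T2 triplet."""

    semi_axes: tuple = (70.0, 90.0, 100.0)
    subdivision: int = 4
    bump_center: tuple | None = None        # None -> default left-cheek spot
    bump_amplitude_T1: float = 3.0          # mm
    bump_amplitude_T2: float = 1.0          # mm
    bump_sigma: float = 15.0                # mm
    max_rotation_deg: float = 5.0           # rigid noise per timepoint
    max_translation_mm: float = 5.0
    vertex_jitter_mm: float = 0.0           # optional Gaussian scanner noise
    seed: int = 0

    def __post_init__(self):
        if self.bump_amplitude_T1 < 0 or self.bump_amplitude_T2 < 0:
            raise ValueError("bump amplitudes must be >= 0")
        if self.bump_amplitude_T2 > self.bump_amplitude_T1:
            raise ValueError("T2 amplitude must not exceed T1 (swelling resolves)")
        if self.bump_sigma <= 0:
            raise ValueError("bump sigma must be > 0")

    def resolved_center(self) -> np.ndarray:
        if self.bump_center is not None:
            return np.asarray(self.bump_center, dtype=np.float64)
        return _ellipsoid_point(DEFAULT_BUMP_DIRECTION, self.semi_axes)


def random_rigid_transform(rng: np.random.Generator, max_rotation_deg: float,
                           max_translation_mm: float) -> RigidTransform:
    """Uniform random axis, rotation angle and translation within the bounds."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_rotation_deg))
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(R, t)


def make_scenario(scenario: SwellingScenario, out_dir=None) -> dict:
    """Build the T0/T1/T2 triplet, landmark set and ground-truth record.

    Returns a dict with in-memory meshes, landmarks, per-timepoint rigid
    perturbations and the analytic added volumes. When ``out_dir`` is given,
    writes t0/t1/t2.ply, landmarks.json and ground_truth.json there.
    """
    rng = np.random.default_rng(scenario.seed)
    base, landmarks = generate_head(scenario.semi_axes, scenario.subdivision)
    center = scenario.resolved_center()
    t1_mesh, added_t1 = add_swelling_bump(base, center, scenario.bump_amplitude_T1,
                                          scenario.bump_sigma)
    t2_mesh, added_t2 = add_swelling_bump(base, center, scenario.bump_amplitude_T2,
                                          scenario.bump_sigma)
    meshes = {"T0": base.copy(), "T1": t1_mesh, "T2": t2_mesh}
    transforms = {}
    for label in ("T0", "T1", "T2"):
        if scenario.max_rotation_deg > 0 or scenario.max_translation_mm > 0:
            t = random_rigid_transform(rng, scenario.max_rotation_deg,
                                       scenario.max_translation_mm)
        else:
            t = RigidTransform.identity()
        transforms[label] = t
        m = meshes[label]
        m.vertices = t.apply(m.vertices)
        if scenario.vertex_jitter_mm > 0:
            m.vertices = m.vertices + rng.normal(
                scale=scenario.vertex_jitter_mm, size=m.vertices.shape)
    moved_landmarks = landmarks.transformed(transforms["T0"])
    record = {
        "scenario": {
            "semi_axes": list(np.asarray(scenario.semi_axes, dtype=float)),
            "subdivision": scenario.subdivision,
            "bump_center": center.tolist(),
            "bump_amplitude_T1": scenario.bump_amplitude_T1,
            "bump_amplitude_T2": scenario.bump_amplitude_T2,
            "bump_sigma": scenario.bump_sigma,
            "max_rotation_deg": scenario.max_rotation_deg,
            "max_translation_mm": scenario.max_translation_mm,
            "vertex_jitter_mm": scenario.vertex_jitter_mm,
            "seed": scenario.seed,
        },
        "analytic_added_volume_T1": added_t1,
        "analytic_added_volume_T2": added_t2,
        "transforms": {k: v.to_json() for k, v in transforms.items()},
    }
    result = {"meshes": meshes, "landmarks": moved_landmarks,
              "transforms": transforms, "ground_truth": record}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, mesh in meshes.items():
            write_mesh(mesh, out_dir / f"{label.lower()}.ply", "ply", binary=True)
            record.setdefault("files", {})[label] = f"{label.lower()}.ply"
        moved_landmarks.save(out_dir / "landmarks.json")
        record["files"]["landmarks"] = "landmarks.json"
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(record, fh, indent=2, sort_keys=True)
    return result
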