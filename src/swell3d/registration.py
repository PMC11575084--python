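"""Rigid placement of facial scans: landmark-based standardized orientation and
trimmed point-to-surface ICP registration.

The canonical anatomical frame is defined by the Frankfurt horizontal plane
(both porions and the left orbitale) and the midsagittal plane (through the
nasion, orthogonal to Frankfurt, containing the porion-midpoint-to-nasion
direction):

* origin — midpoint of the two porions;
* z axis — normal of the Frankfurt plane, pointing superiorly;
* y axis — porion-midpoint -> nasion direction projected into the Frankfurt
  plane (anterior);
* x axis — y x z, pointing toward the subject's left, so the right hemiface
  lies at x <= 0.

All coordinates are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateLandmarksError, InvalidMeshError
from .mesh_io import TriangleMesh
from .spatial import SurfaceIndex

CANONICAL_LANDMARKS = ("porion_left", "porion_right", "orbitale_left")
MIDSAGITTAL_LANDMARKS = ("nasion", "subnasale")
ROI_LANDMARKS = ("zygomatic_superior", "submandibular_inferior",
                 "preauricular_posterior", "midline_anterior")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R p + t (rotation then translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.ascontiguousarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_json(cls, data: dict) -> "RigidTransform":
        return cls(np.array(data["rotation"]), np.array(data["translation"]))


@dataclass
class LandmarkSet:
    """Named anatomical points (mm) plus the operated side ('left'/'right')."""

    points: dict
    side: str = "left"

    def __post_init__(self):
        self.points = {k: np.asarray(v, dtype=np.float64).reshape(3)
                       for k, v in self.points.items()}
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise DegenerateLandmarksError(f"missing landmarks: {missing}")
        for n in names:
            if not np.all(np.isfinite(self.points[n])):
                raise DegenerateLandmarksError(f"landmark '{n}' is not finite")

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({k: t.apply(v) for k, v in self.points.items()}, self.side)

    def to_json(self) -> dict:
        out = {k: v.tolist() for k, v in self.points.items()}
        out["side"] = self.side
        return out

    @classmethod
    def from_json(cls, data: dict) -> "LandmarkSet":
        side = data.get("side", "left")
        return cls({k: v for k, v in data.items() if k != "side"}, side)

    @classmethod
    def load(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls.from_json(json.load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2, sort_keys=True)


@dataclass(frozen=True)
class IcpParams:
    max_iterations: int = 100
    rms_change_tolerance: float = 1e-4   # mm
    trim_fraction: float = 0.10
    outlier_scale: float = 3.0           # also reject d > scale * median(d)
    subsample_size: int = 5000
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.outlier_scale <= 1.0:
            raise ValueError("outlier_scale must be > 1")
        if self.rms_change_tolerance <= 0:
            raise ValueError("rms_change_tolerance must be > 0")

    def with_seed(self, seed: int) -> "IcpParams":
        return replace(self, seed=seed)


@dataclass
class IcpResult:
    transform: RigidTransform
    rms: float           # trimmed RMS residual, mm
    n_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# Landmark orientation
# ---------------------------------------------------------------------------

def orient_by_landmarks(landmarks: LandmarkSet) -> RigidTransform:
    """Transform carrying the scan into the canonical anatomical frame.

    The Frankfurt triplet maps into a z = 0 horizontal plane, the midsagittal
    plane maps to x = 0, and the porion midpoint maps to the origin.
    """
    landmarks.require(CANONICAL_LANDMARKS + ("nasion",))
    p_l = landmarks["porion_left"]
    p_r = landmarks["porion_right"]
    orb = landmarks["orbitale_left"]
    nas = landmarks["nasion"]

    cross = np.cross(p_r - p_l, orb - p_l)
    area = 0.5 * np.linalg.norm(cross)
    if area <= 1.0:  # mm^2
        raise DegenerateLandmarksError(
            f"Frankfurt landmarks nearly collinear (triangle area {area:.3g} mm^2)")
    origin = 0.5 * (p_l + p_r)

    z = cross / np.linalg.norm(cross)
    y_raw = nas - origin
    y = y_raw - z * np.dot(y_raw, z)
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegenerateLandmarksError("nasion lies on the porion axis")
    y = y / ny
    x = np.cross(y, z)
    # z must point superiorly and x toward the subject's left
    if np.dot(x, p_l - p_r) < 0:
        z, x = -z, -x
    R = np.vstack([x, y, z])
    return RigidTransform(R, -R @ origin)


# ---------------------------------------------------------------------------
# Transform application
# ---------------------------------------------------------------------------

def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Map vertices (and vector attributes) through a rigid motion."""
    out = mesh.copy()
    out.vertices = t.apply(mesh.vertices)
    out.vertex_vectors = {k: np.asarray(v) @ t.rotation.T
                          for k, v in mesh.vertex_vectors.items()}
    return out


# ---------------------------------------------------------------------------
# Trimmed point-to-surface ICP
# ---------------------------------------------------------------------------

def fit_rigid_points(p, q):
    """Closed-form least-squares rigid fit p -> q (Kabsch, det-corrected)."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    cp = p.mean(axis=0)
    cq = q.mean(axis=0)
    H = (p - cp).T @ (q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cq - R @ cp)


def _fit_point_to_plane(p, q, n):
    """One linearized point-to-plane rigid step: minimize sum(n.(p' - q))^2.

    Solves the standard small-angle least squares in x = [omega; t] with rows
    [p x n, n] and residuals n.(q - p), then re-orthonormalizes the rotation
    exactly through the rotation vector.
    """
    from scipy.spatial.transform import Rotation
    A = np.hstack([np.cross(p, n), n])
    b = np.einsum("ij,ij->i", n, q - p)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    R = Rotation.from_rotvec(x[:3]).as_matrix()
    return RigidTransform(R, x[3:])


def icp_register(source: TriangleMesh, target: TriangleMesh,
                 params: IcpParams = IcpParams(),
                 init: RigidTransform | None = None) -> IcpResult:
    """Rigidly align ``source`` onto ``target`` by iteratively minimizing
    point-to-surface distances with trimmed outlier rejection.

    Per iteration: a seeded uniform subsample of source vertices is matched to
    its nearest points on the target surface, the worst ``trim_fraction`` of
    correspondences by distance is discarded, and a linearized point-to-plane
    rigid step fitted to the survivors is composed onto the current estimate
    (the plane normals are the target face normals at the foot points; the
    point-to-plane objective is what makes registration of smooth convex
    face surfaces converge in a handful of iterations). Iteration stops at
    ``max_iterations`` or when the trimmed RMS improves by less than
    ``rms_change_tolerance``.
    """
    if source.n_vertices == 0 or source.n_faces == 0:
        raise InvalidMeshError("ICP source mesh is empty")
    if target.n_vertices == 0 or target.n_faces == 0:
        raise InvalidMeshError("ICP target mesh is empty")
    if init is None:
        init = RigidTransform.identity()

    rng = np.random.default_rng(params.seed)
    n = source.n_vertices
    if params.subsample_size < n:
        idx = np.sort(rng.choice(n, size=params.subsample_size, replace=False))
    else:
        idx = np.arange(n)
    pts = source.vertices[idx]
    index = SurfaceIndex(target.vertices, target.faces)
    tri = target.vertices[target.faces]
    face_normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lengths = np.linalg.norm(face_normals, axis=1, keepdims=True)
    lengths[lengths == 0] = 1.0
    face_normals /= lengths

    n_cap = max(6, int(np.ceil((1.0 - params.trim_fraction) * len(pts))))
    n_floor = max(6, len(pts) // 4)
    transform = init
    prev_rms = np.inf
    rms = np.inf
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        moved = transform.apply(pts)
        feet, dist, face_idx = index.query(moved)
        order = np.argsort(dist, kind="stable")[:n_cap]
        # adaptive rejection: once the bulk of the surface is in contact the
        # median residual collapses, and anything far above it (the swelling
        # patch) is excluded from the fit regardless of its size
        threshold = max(params.outlier_scale * float(np.median(dist)), 1e-9)
        adaptive = order[dist[order] <= threshold]
        if len(adaptive) >= n_floor:
            order = adaptive
        rms = float(np.sqrt(np.mean(dist[order] ** 2)))
        if prev_rms - rms < params.rms_change_tolerance:
            converged = True
            break
        prev_rms = rms
        step = _fit_point_to_plane(moved[order], feet[order],
                                   face_normals[face_idx[order]])
        transform = step.compose(transform)
    return IcpResult(transform, rms, it, converged)
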