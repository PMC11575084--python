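"""Region of interest: anatomical boundary half-spaces and plane clipping.

The swelling ROI is the operated hemiface patch bounded superiorly by the
zygomatic arch, inferiorly by the submandibular fossa, posteriorly by the
preauricular region and anteriorly (medially) by the facial midline. In the
canonical frame these four boundaries are realized as axis-aligned planes
through the corresponding landmark points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InconsistentRoiError
from .mesh_io import TriangleMesh
from .registration import ROI_LANDMARKS, LandmarkSet

_EPS = 1e-9  # mm; on-plane snapping tolerance for clipping


@dataclass
class RoiSpec:
    """Intersection of half-spaces, each (point-on-plane, inward unit normal)."""

    half_spaces: list            # [(point (3,), normal (3,)), ...]
    label: str = "roi"

    def __post_init__(self):
        if len(self.half_spaces) < 1:
            raise InconsistentRoiError("RoiSpec needs at least one half-space")
        norm = []
        for point, normal in self.half_spaces:
            point = np.asarray(point, dtype=np.float64).reshape(3)
            normal = np.asarray(normal, dtype=np.float64).reshape(3)
            length = np.linalg.norm(normal)
            if abs(length - 1.0) > 1e-9:
                if length == 0:
                    raise InconsistentRoiError("zero-length ROI plane normal")
                normal = normal / length
            norm.append((point, normal))
        self.half_spaces = norm

    def signed_distances(self, points: np.ndarray) -> np.ndarray:
        """(n_points, n_planes) inward signed distances; >= 0 means inside."""
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        return np.column_stack([(points - p) @ n for p, n in self.half_spaces])

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.all(self.signed_distances(points) >= -_EPS, axis=1)

    def to_json(self) -> dict:
        return {"label": self.label,
                "half_spaces": [{"point": p.tolist(), "normal": n.tolist()}
                                for p, n in self.half_spaces]}

    @classmethod
    def from_json(cls, data: dict) -> "RoiSpec":
        return cls([(h["point"], h["normal"]) for h in data["half_spaces"]],
                   data.get("label", "roi"))

    @classmethod
    def load(cls, path) -> "RoiSpec":
        with open(path) as fh:
            return cls.from_json(json.load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2, sort_keys=True)


def roi_from_landmarks(landmarks: LandmarkSet) -> RoiSpec:
    """Axis-aligned ROI half-spaces from the four boundary landmarks.

    Assumes the landmarks are already in the canonical frame. The operated
    side selects the hemiface: side='left' keeps x >= midline, side='right'
    keeps x <= midline (the canonical x axis points toward the subject's left).
    """
    landmarks.require(ROI_LANDMARKS)
    z_sup = landmarks["zygomatic_superior"][2]
    z_inf = landmarks["submandibular_inferior"][2]
    y_post = landmarks["preauricular_posterior"][1]
    x_mid = landmarks["midline_anterior"][0]
    if z_sup <= z_inf:
        raise InconsistentRoiError(
            f"zygomatic plane (z={z_sup:.2f}) is not above the submandibular "
            f"plane (z={z_inf:.2f})")
    x_sign = 1.0 if landmarks.side == "left" else -1.0
    half_spaces = [
        (np.array([0.0, 0.0, z_sup]), np.array([0.0, 0.0, -1.0])),   # below zygomatic
        (np.array([0.0, 0.0, z_inf]), np.array([0.0, 0.0, 1.0])),    # above submandibular
        (np.array([0.0, y_post, 0.0]), np.array([0.0, 1.0, 0.0])),   # anterior to preauricular
        (np.array([x_mid, 0.0, 0.0]), np.array([x_sign, 0.0, 0.0])), # operated hemiface
    ]
    return RoiSpec(half_spaces, label=f"hemiface_{landmarks.side}")


# ---------------------------------------------------------------------------
# Plane clipping with triangle splitting
# ---------------------------------------------------------------------------

def clip_to_roi(mesh: TriangleMesh, roi: RoiSpec) -> TriangleMesh:
    """Clip a mesh to the ROI, splitting triangles exactly at the planes.

    Triangles fully inside are kept; triangles crossing a boundary plane are
    split, with new vertices placed on the plane and vertex attributes
    interpolated linearly. The result is generally open along clip boundaries.
    An empty result is returned (not raised) when nothing survives.
    """
    out = mesh.copy()
    for point, normal in roi.half_spaces:
        out = _clip_half_space(out, point, normal)
        if out.n_faces == 0:
            break
    return out


def clip_to_roi_solid(mesh: TriangleMesh, roi: RoiSpec) -> tuple[TriangleMesh, int]:
    """Intersect a surface with the ROI as a closed solid; returns (mesh, fills).

    The input is first closed (acquisition holes filled by fan), then clipped
    by each boundary plane in turn with the planar hole capped immediately.
    Every cap lies exactly in its ROI plane, so two scans clipped by the same
    ROI get identical cap geometry where their surfaces agree — their closed
    volumes then cancel exactly in a difference, which a single fan lid over
    the combined non-planar boundary loop does not guarantee. The returned
    fill count includes both acquisition holes and planar caps.
    """
    from .volumetry import close_mesh
    solid, n_filled = close_mesh(mesh)
    for point, normal in roi.half_spaces:
        solid = _clip_half_space(solid, point, normal)
        if solid.n_faces == 0:
            return solid, n_filled
        solid, n = close_mesh(solid)
        n_filled += n
    return solid, n_filled


def _clip_half_space(mesh: TriangleMesh, point, normal) -> TriangleMesh:
    if mesh.n_faces == 0:
        return mesh
    s = (mesh.vertices - point) @ normal
    s[np.abs(s) <= _EPS] = 0.0
    face_s = s[mesh.faces]
    keep_all = np.all(face_s >= 0, axis=1)
    drop_all = np.all(face_s <= 0, axis=1) & ~np.all(face_s == 0, axis=1)
    crossing = ~keep_all & ~drop_all

    vertices = [mesh.vertices]
    scalars = {k: [np.asarray(v, dtype=np.float64)] for k, v in mesh.vertex_scalars.items()}
    vectors = {k: [np.asarray(v, dtype=np.float64)] for k, v in mesh.vertex_vectors.items()}
    colors = [mesh.vertex_colors.astype(np.float64)] if mesh.vertex_colors is not None else None
    next_idx = mesh.n_vertices
    edge_cache: dict = {}
    new_faces = list(mesh.faces[keep_all])

    def cut_edge(i, j):
        nonlocal next_idx
        key = (min(i, j), max(i, j))
        if key in edge_cache:
            return edge_cache[key]
        t = s[i] / (s[i] - s[j])
        vertices.append((mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i]))[None])
        for k in scalars:
            a = scalars[k][0]
            scalars[k].append(np.atleast_1d(a[i] + t * (a[j] - a[i])))
        for k in vectors:
            a = vectors[k][0]
            vectors[k].append((a[i] + t * (a[j] - a[i]))[None])
        if colors is not None:
            a = colors[0]
            colors.append((a[i] + t * (a[j] - a[i]))[None])
        edge_cache[key] = next_idx
        next_idx += 1
        return edge_cache[key]

    for f in mesh.faces[crossing]:
        poly = []
        for e in range(3):
            i, j = int(f[e]), int(f[(e + 1) % 3])
            if s[i] >= 0:
                poly.append(i)
            if (s[i] > 0 and s[j] < 0) or (s[i] < 0 and s[j] > 0):
                poly.append(cut_edge(i, j))
        # fan-triangulate the clipped polygon (3 or 4 vertices)
        for k in range(1, len(poly) - 1):
            tri = (poly[0], poly[k], poly[k + 1])
            if len({*tri}) == 3:
                new_faces.append(np.array(tri, dtype=np.int64))

    all_vertices = np.vstack(vertices)
    faces = (np.array(new_faces, dtype=np.int64).reshape(-1, 3)
             if new_faces else np.zeros((0, 3), dtype=np.int64))
    # drop unreferenced vertices, keeping first-use order stable
    used = np.unique(faces.reshape(-1)) if len(faces) else np.array([], dtype=np.int64)
    remap = np.full(len(all_vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(
        vertices=all_vertices[used],
        faces=remap[faces] if len(faces) else faces,
        vertex_scalars={k: np.concatenate(v)[used] for k, v in scalars.items()},
        vertex_vectors={k: np.vstack(v)[used] for k, v in vectors.items()},
        vertex_colors=(np.clip(np.rint(np.vstack(colors)[used]), 0, 255).astype(np.uint8)
                       if colors is not None else None),
        metadata=dict(mesh.metadata),
    )
    return out
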