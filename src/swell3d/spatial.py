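"""Closest-point-on-surface queries.

Both the trimmed-ICP registration and the model-to-model distance field need
the exact nearest point on a triangle surface for large batches of query
points. Candidate triangles come from a cKDTree over triangle centroids (plus
the faces incident to the nearest vertex); the exact foot point per candidate
is computed with the standard barycentric-region closest-point-on-triangle
construction, fully vectorized.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points, tri_a, tri_b, tri_c):
    """Closest point on each triangle (A,B,C) from each query point.

    All inputs are (n, 3); returns (n, 3) foot points.
    """
    a, b, c = tri_a, tri_b, tri_c
    p = points
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.shape == p.shape else value
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    settle((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    settle((d6 >= 0) & (d5 <= d6), c)                      # vertex C

    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done          # edge AB
    if m.any():
        t = (d1[m] / (d1[m] - d3[m]))[:, None]
        out[m] = a[m] + t * ab[m]
        done[m] = True
    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done          # edge AC
    if m.any():
        t = (d2[m] / (d2[m] - d6[m]))[:, None]
        out[m] = a[m] + t * ac[m]
        done[m] = True
    va = d3 * d6 - d5 * d4
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0) & ~done   # edge BC
    if m.any():
        t = ((d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m])))[:, None]
        out[m] = b[m] + t * (c[m] - b[m])
        done[m] = True
    m = ~done                                              # interior
    if m.any():
        denom = va[m] + vb[m] + vc[m]
        v = (vb[m] / denom)[:, None]
        w = (vc[m] / denom)[:, None]
        out[m] = a[m] + v * ab[m] + w * ac[m]
    return out


class SurfaceIndex:
    """Spatial index for nearest-point-on-surface queries against one mesh."""

    def __init__(self, vertices, faces, k_candidates: int = 24):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        if len(self.faces) == 0:
            raise ValueError("cannot index an empty mesh")
        self.tri = self.vertices[self.faces]              # (m, 3, 3)
        centroids = self.tri.mean(axis=1)
        self._ctree = cKDTree(centroids)
        self._vtree = cKDTree(self.vertices)
        # faces incident to each vertex, padded square matrix for fancy indexing
        order = np.argsort(self.faces.reshape(-1), kind="stable")
        flat_face = np.repeat(np.arange(len(self.faces)), 3)[order]
        flat_vert = self.faces.reshape(-1)[order]
        starts = np.searchsorted(flat_vert, np.arange(len(self.vertices)))
        ends = np.searchsorted(flat_vert, np.arange(len(self.vertices)), side="right")
        width = max(1, int((ends - starts).max()))
        self._incident = np.zeros((len(self.vertices), width), dtype=np.int64)
        for v in range(len(self.vertices)):
            inc = flat_face[starts[v]:ends[v]]
            self._incident[v, :len(inc)] = inc
            self._incident[v, len(inc):] = inc[0] if len(inc) else 0
        self.k = min(k_candidates, len(self.faces))

    def query(self, points):
        """Nearest surface points.

        Returns (foot_points (n,3), distances (n,), face_indices (n,)).
        """
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        n = len(points)
        _, cand = self._ctree.query(points, k=self.k)
        cand = np.atleast_2d(cand.reshape(n, -1))
        _, nearest_v = self._vtree.query(points)
        cand = np.hstack([cand, self._incident[nearest_v]])
        k = cand.shape[1]
        flat = cand.reshape(-1)
        pts = np.repeat(points, k, axis=0)
        feet = closest_point_on_triangles(pts, self.tri[flat, 0],
                                          self.tri[flat, 1], self.tri[flat, 2])
        d2 = np.einsum("ij,ij->i", pts - feet, pts - feet).reshape(n, k)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        foot = feet.reshape(n, k, 3)[rows, best]
        face_idx = cand[rows, best]
        return foot, np.sqrt(d2[rows, best]), face_idx
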