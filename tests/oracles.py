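"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: volume by explicit
tetrahedron decomposition against an interior apex, volume by column
integration on a fixed-pitch 2D grid (a voxelization-style oracle), and
closest points by brute force over all triangles.
"""

import numpy as np


def tetrahedron_volume(vertices, faces, apex=None):
    """Signed volume by summing tetrahedra (apex, v0, v1, v2) over all faces."""
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    if apex is None:
        apex = vertices.mean(axis=0)
    tri = vertices[faces] - np.asarray(apex, dtype=np.float64)
    return float(np.einsum("ij,ij->i", tri[:, 0],
                           np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def column_volume(vertices, faces, pitch=0.2):
    """Volume of a closed mesh by vertical-column integration on a 2D grid.

    For each grid column (pixel center in xy) the crossing heights with every
    triangle are found by half-open 2D point-in-triangle tests; sorted
    crossings are paired into inside intervals and their lengths summed. The
    grid is offset by an irrational fraction of the pitch so columns avoid
    triangle edges.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    lo = vertices.min(axis=0)[:2] - pitch
    hi = vertices.max(axis=0)[:2] + pitch
    jitter = pitch * (np.sqrt(2.0) - 1.0) / 8.0
    xs = np.arange(lo[0] + jitter, hi[0], pitch)
    ys = np.arange(lo[1] + 2.0 * jitter, hi[1], pitch)
    nx, ny = len(xs), len(ys)
    crossings = [[] for _ in range(nx * ny)]
    tri = vertices[faces]
    for t in tri:
        txy = t[:, :2]
        mn = txy.min(axis=0)
        mx = txy.max(axis=0)
        i0 = max(0, int(np.ceil((mn[0] - xs[0]) / pitch)))
        i1 = min(nx - 1, int(np.floor((mx[0] - xs[0]) / pitch)))
        j0 = max(0, int(np.ceil((mn[1] - ys[0]) / pitch)))
        j1 = min(ny - 1, int(np.floor((mx[1] - ys[0]) / pitch)))
        if i1 < i0 or j1 < j0:
            continue
        gx, gy = np.meshgrid(xs[i0:i1 + 1], ys[j0:j1 + 1], indexing="ij")
        px = gx.ravel()
        py = gy.ravel()
        d = np.column_stack([px, py])
        v0 = txy[1] - txy[0]
        v1 = txy[2] - txy[0]
        den = v0[0] * v1[1] - v0[1] * v1[0]
        if den == 0:
            continue
        dp = d - txy[0]
        a = (dp[:, 0] * v1[1] - dp[:, 1] * v1[0]) / den
        b = (v0[0] * dp[:, 1] - v0[1] * dp[:, 0]) / den
        inside = (a > 0) & (b > 0) & (a + b < 1)
        if not inside.any():
            continue
        z = t[0, 2] + a[inside] * (t[1, 2] - t[0, 2]) + b[inside] * (t[2, 2] - t[0, 2])
        ii = (np.repeat(np.arange(i0, i1 + 1), j1 - j0 + 1)[inside] * ny
              + np.tile(np.arange(j0, j1 + 1), i1 - i0 + 1)[inside])
        for col, height in zip(ii, z):
            crossings[col].append(height)
    total = 0.0
    for col in crossings:
        if len(col) < 2:
            continue
        col = sorted(col)
        for k in range(0, len(col) - 1, 2):
            total += col[k + 1] - col[k]
    return total * pitch * pitch


def brute_force_closest(points, vertices, faces):
    """Exact nearest point on the surface by testing every triangle."""
    from swell3d.spatial import closest_point_on_triangles
    points = np.asarray(points, dtype=np.float64)
    tri = np.asarray(vertices, dtype=np.float64)[np.asarray(faces, dtype=np.int64)]
    best_d = np.full(len(points), np.inf)
    best_p = np.zeros_like(points)
    for a, b, c in tri:
        feet = closest_point_on_triangles(points,
                                          np.broadcast_to(a, points.shape),
                                          np.broadcast_to(b, points.shape),
                                          np.broadcast_to(c, points.shape))
        d = np.linalg.norm(points - feet, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_p[better] = feet[better]
    return best_p, best_d
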