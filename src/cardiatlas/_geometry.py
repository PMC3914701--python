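"""Vectorised triangle-mesh geometry kernels.

Closest point on a triangle soup (Ericson's region classification) and
line/mesh intersection (Möller-Trumbore, signed line parameter), both
batched over query points with chunking to bound memory.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _closest_on_tris(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point on each triangle (broadcast (N, T, 3))."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    eps = 1e-300
    # interior (barycentric) candidate
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < eps, eps, denom)
    v_in = vb / denom
    w_in = vc / denom
    out = a + ab * v_in[..., None] + ac * w_in[..., None]

    # edge BC
    t_bc = (d4 - d3) / np.where(np.abs((d4 - d3) + (d5 - d6)) < eps, eps, (d4 - d3) + (d5 - d6))
    on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(on_bc[..., None], b + (c - b) * t_bc[..., None], out)
    # edge AC
    t_ac = d2 / np.where(np.abs(d2 - d6) < eps, eps, d2 - d6)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(on_ac[..., None], a + ac * t_ac[..., None], out)
    # edge AB
    t_ab = d1 / np.where(np.abs(d1 - d3) < eps, eps, d1 - d3)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(on_ab[..., None], a + ab * t_ab[..., None], out)
    # vertices
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, out)
    return out


def _tri_diameter(tri: np.ndarray) -> float:
    """Upper bound on any triangle's diameter (max edge length)."""
    e = np.linalg.norm(
        np.stack(
            [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0], tri[:, 2] - tri[:, 1]]
        ),
        axis=-1,
    )
    return float(e.max()) if e.size else 0.0


def closest_point_on_mesh(
    points: np.ndarray,
    vertices: np.ndarray,
    triangles: np.ndarray,
    chunk: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest point on a triangle soup for each query point.

    Candidate triangles are pruned with a KD-tree: the nearest mesh vertex
    at distance d bounds the closest-point distance, so only triangles
    whose centroid lies within d + (max triangle diameter) can hold the
    optimum — the pruning is exact, not approximate.

    Returns ``(closest_points (N,3), distances (N,), triangle_ids (N,))``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    verts = np.asarray(vertices, dtype=float)
    tris = np.asarray(triangles)
    tri = verts[tris]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    n = len(pts)
    closest = np.empty((n, 3))
    dist = np.empty(n)
    tid = np.empty(n, dtype=np.int64)

    if len(tris) <= 512:
        for s in range(0, n, chunk):
            p = pts[s : s + chunk, None, :]
            cand = _closest_on_tris(p, a[None], b[None], c[None])
            d2 = ((cand - p) ** 2).sum(-1)
            j = np.argmin(d2, axis=1)
            rows = np.arange(len(j))
            closest[s : s + chunk] = cand[rows, j]
            dist[s : s + chunk] = np.sqrt(d2[rows, j])
            tid[s : s + chunk] = j
        return closest, dist, tid

    diam = _tri_diameter(tri)
    d_vert, _ = cKDTree(verts).query(pts)
    centroids = tri.mean(axis=1)
    ctree = cKDTree(centroids)
    cand_lists = ctree.query_ball_point(pts, d_vert + diam + 1e-9)
    for i, cand_idx in enumerate(cand_lists):
        idx = np.asarray(cand_idx, dtype=np.int64)
        p = pts[i][None, :]
        cand = _closest_on_tris(p, a[idx], b[idx], c[idx])
        d2 = ((cand - p) ** 2).sum(-1)
        j = int(np.argmin(d2))
        closest[i] = cand[j]
        dist[i] = np.sqrt(d2[j])
        tid[i] = idx[j]
    return closest, dist, tid


def _mt_nearest(oc, dc, v0, e1, e2, cap: float | None):
    """Möller-Trumbore over one origin/direction against candidate tris.

    Returns (t, hit) for the intersection of smallest |t| (optionally
    limited to |t| <= cap).
    """
    h = np.cross(dc, e2)
    det = (e1 * h).sum(-1)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    sv = oc - v0
    u = inv * (sv * h).sum(-1)
    q = np.cross(sv, e1)
    v = inv * (q * dc).sum(-1)
    t = inv * (e2 * q).sum(-1)
    eps = 1e-9
    valid = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps)
    if cap is not None:
        valid &= np.abs(t) <= cap
    abst = np.where(valid, np.abs(t), np.inf)
    j = int(np.argmin(abst)) if abst.size else 0
    if abst.size == 0 or not np.isfinite(abst[j]):
        return np.nan, False
    return float(t[j]), True


def line_mesh_nearest_t(
    origins: np.ndarray,
    directions: np.ndarray,
    vertices: np.ndarray,
    triangles: np.ndarray,
    max_distance: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect infinite lines with a mesh; return the signed parameter of
    the intersection nearest each origin.

    ``t`` is in units of the direction vector's length (pass unit vectors
    for mm).  ``max_distance`` (scalar or per-line) caps the search to
    ``|t| <= max_distance`` and enables KD-tree pruning of candidate
    triangles, which makes the query local and fast; within the cap the
    result is exact.  Returns ``(t (N,), hit (N,) bool)``; ``t`` is NaN
    where no admissible intersection exists.
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    tri = np.asarray(vertices, dtype=float)[np.asarray(triangles)]
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    n = len(o)
    t_out = np.full(n, np.nan)
    hit = np.zeros(n, dtype=bool)

    if max_distance is None or len(tri) <= 512:
        caps = None if max_distance is None else np.broadcast_to(
            np.asarray(max_distance, dtype=float), (n,)
        )
        for i in range(0, n, 64):
            sl = slice(i, min(i + 64, n))
            for k in range(sl.start, sl.stop):
                cap = None if caps is None else float(caps[k])
                t_out[k], hit[k] = _mt_nearest(
                    o[k][None], d[k][None], v0, e1, e2, cap
                )
        return t_out, hit

    # Prune against the capped segment of each line: sample it at the
    # triangle-diameter scale and take every triangle whose centroid falls
    # within one diameter of a sample.  Any triangle intersecting the
    # segment has a point on it, hence a centroid within (sample step/2 +
    # diameter) of some sample — covered by the chosen radius.
    caps = np.broadcast_to(np.asarray(max_distance, dtype=float), (n,)).astype(float)
    diam = max(_tri_diameter(tri), 1e-6)
    ctree = cKDTree(tri.mean(axis=1))
    for i in range(n):
        cap = float(caps[i])
        m = max(int(np.ceil(2 * cap / diam)) + 1, 2)
        ts = np.linspace(-cap, cap, m)
        samples = o[i] + ts[:, None] * d[i]
        lists = ctree.query_ball_point(samples, 1.6 * diam)
        cand = {j for lst in lists for j in lst}
        if not cand:
            continue
        idx = np.fromiter(cand, dtype=np.int64)
        t_out[i], hit[i] = _mt_nearest(
            o[i][None], d[i][None], v0[idx], e1[idx], e2[idx], cap
        )
    return t_out, hit
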