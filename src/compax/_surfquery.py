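"""Vectorized point-vs-triangulated-surface queries.

Containment uses even-odd ray casting with a fixed irrational ray
direction (robust against axis-aligned degeneracies of lattice points);
closest-point projection clamps barycentric coordinates per triangle.
Both run chunked-dense against all faces, which is fast for the surface
sizes used here (hundreds to a few thousand triangles).
"""

from __future__ import annotations

import numpy as np

_RAY = np.array([0.57735026919, 0.26726124191, 0.77151674981])
_RAY /= np.linalg.norm(_RAY)


def contains(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray,
             chunk: int = 2048) -> np.ndarray:
    """Even-odd containment test for ``points`` against a closed surface."""
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    pvec = np.cross(_RAY, e2)  # (F, 3)
    det = np.einsum("fi,fi->f", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    points = np.atleast_2d(points)
    out = np.zeros(points.shape[0], dtype=bool)
    for s in range(0, points.shape[0], chunk):
        p = points[s : s + chunk]
        tvec = p[:, None, :] - v0[None, :, :]  # (P, F, 3)
        u = np.einsum("pfi,fi->pf", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("pfi,i->pf", qvec, _RAY) * inv_det
        t = np.einsum("pfi,fi->pf", qvec, e2) * inv_det
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
        out[s : s + chunk] = (hit.sum(axis=1) % 2) == 1
    return out


def closest_point(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray,
                  chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Closest points on the surface and their distances, per query point."""
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    ab = b - a
    ac = c - a

    points = np.atleast_2d(points)
    best = np.empty_like(points)
    bdist = np.full(points.shape[0], np.inf)
    for s in range(0, points.shape[0], chunk):
        p = points[s : s + chunk]
        cp = _closest_on_tris(p, a, ab, ac)  # (P, F, 3)
        d2 = ((cp - p[:, None, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
        rows = np.arange(p.shape[0])
        best[s : s + chunk] = cp[rows, idx]
        bdist[s : s + chunk] = np.sqrt(d2[rows, idx])
    return best, bdist


def signed_distance(vertices: np.ndarray, faces: np.ndarray,
                    points: np.ndarray) -> np.ndarray:
    """Distance to the surface, positive inside, negative outside."""
    _, d = closest_point(vertices, faces, points)
    inside = contains(vertices, faces, points)
    return np.where(inside, d, -d)


def _closest_on_tris(p: np.ndarray, a: np.ndarray, ab: np.ndarray,
                     ac: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query point (Ericson).

    ``p``: (P, 3); ``a``, ``ab``, ``ac``: (F, 3).  Returns (P, F, 3).
    """
    P, F = p.shape[0], a.shape[0]
    ap = p[:, None, :] - a[None, :, :]  # (P, F, 3)
    d1 = np.einsum("fi,pfi->pf", ab, ap)
    d2 = np.einsum("fi,pfi->pf", ac, ap)
    bp = ap - ab[None, :, :]
    d3 = np.einsum("fi,pfi->pf", ab, bp)
    d4 = np.einsum("fi,pfi->pf", ac, bp)
    cp_ = ap - ac[None, :, :]
    d5 = np.einsum("fi,pfi->pf", ab, cp_)
    d6 = np.einsum("fi,pfi->pf", ac, cp_)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    v = np.where(np.abs(denom) > 0, vb / np.where(denom == 0, 1, denom), 0.0)
    w = np.where(np.abs(denom) > 0, vc / np.where(denom == 0, 1, denom), 0.0)

    # interior case
    out = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

    # edge/vertex regions overwrite in priority order
    # region edge AC
    wc = np.clip(np.where(d6 - d5 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0), 0, 1)
    mask = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(mask[..., None], a[None] + wc[..., None] * ac[None], out)
    # region edge BC
    t_bc = np.clip(
        np.where((d4 - d3) + (d5 - d6) != 0,
                 (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1, (d4 - d3) + (d5 - d6)),
                 0), 0, 1)
    b_pt = a + ab
    mask = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(mask[..., None], b_pt[None] + t_bc[..., None] * (ac - ab)[None], out)
    # region edge AB
    vab = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0), 0, 1)
    mask = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(mask[..., None], a[None] + vab[..., None] * ab[None], out)
    # vertex regions
    mask = (d1 <= 0) & (d2 <= 0)  # A
    out = np.where(mask[..., None], np.broadcast_to(a[None], out.shape), out)
    mask = (d3 >= 0) & (d4 <= d3)  # B
    out = np.where(mask[..., None], np.broadcast_to(b_pt[None], out.shape), out)
    mask = (d6 >= 0) & (d5 <= d6)  # C
    out = np.where(mask[..., None], np.broadcast_to((a + ac)[None], out.shape), out)
    return out
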