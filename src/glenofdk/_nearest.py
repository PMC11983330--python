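"""Nearest-point queries against a fixed triangle mesh.

Candidate triangles are culled with a cKDTree over face centroids, then the
exact closest point on each candidate triangle is computed (Ericson's
region-based projection), vectorised over query points.  The master surface in
the contact model is static, so the tree is built once per surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest points on triangles ``tri`` (n,3,3) to query points ``p`` (n,3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
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

    m = (d1 <= 0) & (d2 <= 0)  # vertex A
    out[m] = a[m]
    done |= m
    m = (d3 >= 0) & (d4 <= d3) & ~done  # vertex B
    out[m] = b[m]
    done |= m
    m = (d6 >= 0) & (d5 <= d6) & ~done  # vertex C
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done  # edge AB
    denom = np.where(np.abs(d1 - d3) < 1e-30, 1.0, d1 - d3)
    v = np.clip(d1 / denom, 0.0, 1.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done  # edge AC
    denom = np.where(np.abs(d2 - d6) < 1e-30, 1.0, d2 - d6)
    w = np.clip(d2 / denom, 0.0, 1.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0) & ~done  # edge BC
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(np.abs(denom) < 1e-30, 1.0, denom)
    w = np.clip((d4 - d3) / denom, 0.0, 1.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-30, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class MeshNearest:
    """Reusable nearest-point structure for one triangle mesh."""

    def __init__(self, mesh, k: int = 8):
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        self.face_normals = np.asarray(mesh.face_normals, dtype=float)
        self._centroids = self.triangles.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self._k = min(k, len(self.triangles))

    def query(self, points: np.ndarray):
        """Return (nearest points, face indices) for query ``points`` (n,3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(pts, k=self._k)
        idx = np.atleast_2d(idx)
        n, k = idx.shape
        flat = idx.reshape(-1)
        rep = np.repeat(pts, k, axis=0)
        cands = _closest_on_triangles(rep, self.triangles[flat])
        d2 = np.einsum("ij,ij->i", rep - cands, rep - cands).reshape(n, k)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        nearest = cands.reshape(n, k, 3)[rows, best]
        faces = idx[rows, best]
        return nearest, faces
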