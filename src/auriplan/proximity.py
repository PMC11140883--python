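"""Exact closest-point-on-surface queries against a triangle mesh.

A cKDTree over triangle centroids prunes candidates; the surviving
triangles get an exact point-to-triangle test (barycentric region walk).
Correctness guarantee: any triangle closer to the query than the current
best must have a centroid within ``best + r_max`` of the query, where
``r_max`` is the largest centroid-to-corner distance over the mesh, so the
second-stage ball query cannot miss the true minimiser.  Degenerate
(zero-area) faces are excluded.  Ties on distance resolve to the lowest
triangle index.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TriMesh

__all__ = ["SurfaceQuery", "closest_point_triangles"]


def closest_point_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``tri[i]`` to ``points[i]``, both (n, 3[, 3]).

    Vectorised barycentric-region classification (Ericson, *Real-Time
    Collision Detection*, §5.1.5).
    """
    p = np.asarray(points, dtype=float)
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

    # vertex A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex B
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    # vertex C
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    if m.any():
        denom = va + vb + vc
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(denom != 0, vb / np.where(denom == 0, 1, denom), 0.0)
            w = np.where(denom != 0, vc / np.where(denom == 0, 1, denom), 0.0)
        out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceQuery:
    """Reusable closest-point structure for one reference mesh."""

    def __init__(self, mesh: TriMesh):
        good = ~mesh.degenerate_faces
        if not good.any():
            raise ValueError("mesh has no non-degenerate faces")
        self.mesh = mesh
        self.face_indices = np.flatnonzero(good)
        self.triangles = mesh.triangles[good]
        self.normals = mesh.face_normals[good]
        self._centroids = self.triangles.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self._r_max = float(
            np.linalg.norm(self.triangles - self._centroids[:, None, :], axis=2).max()
        )

    def query(self, points: np.ndarray):
        """Return ``(closest, distance, face_index)`` for each query point.

        ``face_index`` refers to the original mesh face numbering; among
        exactly equidistant faces the lowest index wins.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(p)
        # stage 1: exact distance to the triangle owning the nearest centroid
        _, near = self._tree.query(p, k=1)
        near = np.atleast_1d(near)
        d_upper = np.linalg.norm(
            closest_point_triangles(p, self.triangles[near]) - p, axis=1
        )
        # stage 2: all triangles whose centroid could beat that bound
        radii = d_upper + self._r_max + 1e-12
        lists = self._tree.query_ball_point(p, radii)

        closest = np.empty((n, 3))
        dist = np.empty(n)
        fidx = np.empty(n, dtype=np.int64)
        flat = np.concatenate([np.sort(ix) for ix in lists]).astype(np.int64)
        counts = np.array([len(ix) for ix in lists])
        offsets = np.concatenate([[0], np.cumsum(counts)])
        rep = np.repeat(np.arange(n), counts)
        cand_pts = closest_point_triangles(p[rep], self.triangles[flat])
        cand_d = np.linalg.norm(cand_pts - p[rep], axis=1)
        for i in range(n):
            s = slice(offsets[i], offsets[i + 1])
            # candidates sorted by face index: argmin returns lowest index on ties
            j = int(np.argmin(cand_d[s])) + offsets[i]
            dist[i] = cand_d[j]
            closest[i] = cand_pts[j]
            fidx[i] = flat[j]
        return closest, dist, self.face_indices[fidx]

    def signed_distance(self, points: np.ndarray):
        """Distances signed by the nearest face's outward normal (+ = outside)."""
        closest, dist, fidx = self.query(points)
        p = np.atleast_2d(np.asarray(points, dtype=float))
        local = np.searchsorted(self.face_indices, fidx)
        side = np.einsum("ij,ij->i", p - closest, self.normals[local])
        return np.where(side < 0, -dist, dist), closest, fidx
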