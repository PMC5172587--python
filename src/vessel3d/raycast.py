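"""Ray casting and exact point-to-surface distances on triangle meshes.

Both the shape-diameter function and volumetric obscurance need millions of
first-hit ray queries, and the Hausdorff QC needs exact nearest-surface
distances.  This module provides a uniform-grid acceleration structure with a
vectorised 3-D DDA traversal and Möller–Trumbore intersection, plus a
KD-tree-pruned exact point-to-triangle distance query.  Everything is pure
numpy/scipy and fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["TriangleGrid", "nearest_surface_distance", "point_triangle_distance"]

_EPS = 1e-9


def _moller_trumbore(orig: np.ndarray, direc: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Per-pair ray/triangle intersection parameter t (inf where no hit)."""
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(direc, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    t = np.full(len(orig), np.inf)
    ok = np.abs(det) > 1e-12
    if not ok.any():
        return t
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    tvec = orig - tri[:, 0]
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", direc, qvec) * inv
    tt = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (tt > 0)
    t[hit] = tt[hit]
    return t


class TriangleGrid:
    """Uniform spatial hash of a triangle soup for first-hit ray queries.

    Triangles are binned into every grid cell their bounding box overlaps;
    rays walk cells front-to-back with a vectorised DDA and stop as soon as
    the best hit lies inside the already-traversed region.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, cell_size: float | None = None):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces, int)
        self.tri = self.vertices[self.faces]  # (M, 3, 3)
        if len(self.tri) == 0:
            raise ValueError("cannot build a ray grid on an empty mesh")
        lo = self.tri.min(axis=(0, 1))
        hi = self.tri.max(axis=(0, 1))
        span = np.maximum(hi - lo, 1e-6)
        if cell_size is None:
            # about one triangle per occupied surface cell: keeps candidate
            # batches small so the DDA loop dominates, which vectorises well
            tri_extent = np.median((self.tri.max(axis=1) - self.tri.min(axis=1)).max(axis=1))
            cell_size = float(max(0.9 * max(tri_extent, 1e-6), span.max() / 256))
        self.cell = float(cell_size)
        self.lo = lo - 1e-6
        self.res = np.maximum(np.ceil(span / self.cell).astype(np.int64) + 1, 1)

        tlo = np.floor((self.tri.min(axis=1) - self.lo) / self.cell).astype(np.int64)
        thi = np.floor((self.tri.max(axis=1) - self.lo) / self.cell).astype(np.int64)
        ext = thi - tlo + 1
        counts = ext.prod(axis=1)
        offs = np.concatenate([[0], np.cumsum(counts)])
        tri_ids = np.repeat(np.arange(len(self.tri)), counts)
        cell_ids = np.empty(offs[-1], np.int64)
        # enumerate covered cells, grouped by identical (ex, ey, ez) extent shape
        for shape in np.unique(ext, axis=0):
            sel = np.flatnonzero((ext == shape).all(axis=1))
            local = np.stack(
                np.meshgrid(*[np.arange(int(e)) for e in shape], indexing="ij"), axis=-1
            ).reshape(-1, 3)
            cells = tlo[sel][:, None, :] + local[None, :, :]
            flat = (cells[..., 0] * self.res[1] + cells[..., 1]) * self.res[2] + cells[..., 2]
            m = len(local)
            dst = offs[sel][:, None] + np.arange(m)[None, :]
            cell_ids[dst.ravel()] = flat.ravel()
        order = np.argsort(cell_ids, kind="stable")
        cell_ids = cell_ids[order]
        self._tri_list = tri_ids[order]
        self._keys, starts = np.unique(cell_ids, return_index=True)
        self._offsets = np.concatenate([starts, [len(cell_ids)]])
        fn = np.cross(self.tri[:, 1] - self.tri[:, 0], self.tri[:, 2] - self.tri[:, 0])
        self.face_normals = fn / np.maximum(np.linalg.norm(fn, axis=1, keepdims=True), _EPS)

    def _candidates(self, flat_cells: np.ndarray):
        """CSR lookup: ragged triangle lists for an array of flat cell ids."""
        idx = np.searchsorted(self._keys, flat_cells)
        idx = np.clip(idx, 0, len(self._keys) - 1)
        ok = self._keys[idx] == flat_cells
        starts = np.where(ok, self._offsets[idx], 0)
        counts = np.where(ok, self._offsets[idx + 1] - self._offsets[idx], 0)
        return starts, counts

    def first_hit(
        self,
        origins: np.ndarray,
        directions: np.ndarray,
        max_dist: float = np.inf,
        min_dist: float = 1e-6,
        backface_only: bool = False,
    ) -> np.ndarray:
        """Distance to the first triangle hit along each ray (inf if none).

        ``min_dist`` discards immediate self-hits when rays start on the
        surface they are cast from.  With ``backface_only`` a hit counts only
        if the ray strikes the triangle from its back side (the interior of
        an outward-oriented surface) — grazing front-face hits from rays
        skimming along the surface are traversed through.
        """
        origins = np.asarray(origins, float).reshape(-1, 3)
        directions = np.asarray(directions, float).reshape(-1, 3)
        n = len(origins)
        best = np.full(n, np.inf)
        if n == 0:
            return best
        chunk = 65_536
        if n > chunk:  # bound the working-set memory of the DDA state
            for s in range(0, n, chunk):
                best[s : s + chunk] = self.first_hit(
                    origins[s : s + chunk], directions[s : s + chunk],
                    max_dist, min_dist, backface_only,
                )
            return best
        d = directions / np.maximum(np.linalg.norm(directions, axis=1, keepdims=True), _EPS)

        # clip rays to the grid's bounding box (slab test)
        gmin, gmax = self.lo, self.lo + self.res * self.cell
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(np.abs(d) > _EPS, 1.0 / d, np.inf)
        t0 = (gmin - origins) * inv
        t1 = (gmax - origins) * inv
        t_enter = np.minimum(t0, t1).max(axis=1)
        t_exit = np.maximum(t0, t1).min(axis=1)
        t_cur = np.maximum(t_enter, 0.0) + 1e-9
        alive = (t_exit > t_cur) & (t_cur < max_dist)

        cell_idx = np.floor((origins + t_cur[:, None] * d - self.lo) / self.cell).astype(np.int64)
        cell_idx = np.clip(cell_idx, 0, self.res - 1)
        step = np.where(d > 0, 1, -1).astype(np.int64)
        next_bound = self.lo + (cell_idx + (step > 0)) * self.cell
        t_max = np.where(np.abs(d) > _EPS, (next_bound - origins) * inv, np.inf)
        t_delta = np.where(np.abs(d) > _EPS, self.cell * np.abs(inv), np.inf)

        ridx = np.arange(n)
        while alive.any():
            a = np.flatnonzero(alive)
            flat = (cell_idx[a, 0] * self.res[1] + cell_idx[a, 1]) * self.res[2] + cell_idx[a, 2]
            starts, counts = self._candidates(flat)
            tot = int(counts.sum())
            if tot:
                rays = np.repeat(a, counts)
                ends = np.cumsum(counts)
                pos = np.arange(tot) - np.repeat(ends - counts, counts)
                tris = self._tri_list[np.repeat(starts, counts) + pos]
                t = _moller_trumbore(origins[rays], d[rays], self.tri[tris])
                valid = (t >= min_dist) & (t <= max_dist)
                if backface_only:
                    facing = np.einsum(
                        "ij,ij->i", d[rays], self.face_normals[tris]
                    )
                    valid &= facing > 1e-9
                if valid.any():
                    np.minimum.at(best, rays[valid], t[valid])
            # advance DDA: step the axis with the smallest t_max
            ax = np.argmin(t_max[a], axis=1)
            t_next = t_max[a, ax]
            cell_idx[a, ax] += step[a, ax]
            t_max[a, ax] += t_delta[a, ax]
            # a recorded hit is final once it lies before the region still to traverse
            out_of_grid = (cell_idx[a, ax] < 0) | (cell_idx[a, ax] >= self.res[ax])
            done = (best[a] <= t_next) | out_of_grid | (t_next > max_dist) | (t_next >= t_exit[a])
            alive[a[done]] = False
        return best


# ---------------------------------------------------------------------------
# exact point-to-triangle distances


def point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from each point to its paired triangle (vectorised).

    Projects onto the triangle plane; if the barycentric foot lies outside,
    the distance is the minimum over the three edge segments.
    """
    points = np.asarray(points, float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    nrm = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", nrm, nrm)
    # barycentric coordinates of the in-plane projection
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    safe = np.abs(denom) > 1e-18
    v = np.where(safe, (d11 * d20 - d01 * d21) / np.where(safe, denom, 1), -1)
    w = np.where(safe, (d00 * d21 - d01 * d20) / np.where(safe, denom, 1), -1)
    inside = (v >= 0) & (w >= 0) & (v + w <= 1) & (nn > 1e-18)
    dist_plane = np.abs(np.einsum("ij,ij->i", ap, nrm)) / np.sqrt(np.maximum(nn, 1e-300))

    def _seg(p, s0, s1):
        sv = s1 - s0
        tt = np.einsum("ij,ij->i", p - s0, sv) / np.maximum(
            np.einsum("ij,ij->i", sv, sv), 1e-300
        )
        tt = np.clip(tt, 0.0, 1.0)
        return np.linalg.norm(p - (s0 + tt[:, None] * sv), axis=1)

    d_edges = np.minimum.reduce([_seg(points, a, b), _seg(points, b, c), _seg(points, c, a)])
    return np.where(inside, dist_plane, d_edges)


def nearest_surface_distance(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Exact nearest distance from each query point to a triangle mesh surface.

    A KD-tree over the target vertices gives an upper bound per point; only
    triangles whose circumball can beat that bound are tested exactly, so the
    result equals the brute-force all-pairs minimum.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, int)
    if len(faces) == 0:
        raise ValueError("target mesh has no faces; distance undefined")
    tri = vertices[faces]
    centroids = tri.mean(axis=1)
    tri_radius = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)

    # the nearest target vertex gives a per-point upper bound; a triangle can
    # only beat it when its centroid lies within bound + its own circumradius.
    # Triangles are binned by circumradius so the few oversized ones (healing
    # caps) do not inflate the search radius of the ordinary ones.
    vtree = cKDTree(vertices[np.unique(faces)])
    d_ub, _ = vtree.query(points, k=1)

    r_med = max(float(np.median(tri_radius)), 1e-9)
    bin_edges = [0.0, 1.5 * r_med, 3 * r_med, 6 * r_med, np.inf]
    bins = []
    for lo_e, hi_e in zip(bin_edges[:-1], bin_edges[1:]):
        ids = np.flatnonzero((tri_radius > lo_e) & (tri_radius <= hi_e))
        if len(ids):
            bins.append(
                (ids, cKDTree(centroids[ids]), float(tri_radius[ids].max()))
            )

    out = np.empty(len(points))
    chunk = 2048
    for s in range(0, len(points), chunk):
        pts = points[s : s + chunk]
        res = d_ub[s : s + chunk].copy()
        for ids, ctree, r_max in bins:
            groups = ctree.query_ball_point(pts, res + r_max + 1e-9)
            counts = np.array([len(g) for g in groups])
            if not counts.sum():
                continue
            pid = np.repeat(np.arange(len(pts)), counts)
            tid = ids[np.concatenate([np.asarray(g, int) for g in groups if g])]
            d = point_triangle_distance(pts[pid], tri[tid])
            np.minimum.at(res, pid, d)
        out[s : s + chunk] = res
    return out
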