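"""Independent brute-force oracles used by the test suite.

Implemented directly from definitions (shifted-array maxima, flood fill by
iterated single-voxel dilation, explicit kernel sums, all-pairs
point-triangle distances) — deliberately not sharing code paths with the
package implementations they check.
"""

import numpy as np


def ball_offsets(r):
    """Integer offsets of a Euclidean ball of radius r (voxels)."""
    rng = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = dz**2 + dy**2 + dx**2 <= r**2
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def _shift_reduce(vol, offsets, reduce_fn, pad_value):
    r = int(np.abs(offsets).max())
    padded = np.pad(vol.astype(np.int32), r, constant_values=pad_value)
    acc = None
    n = vol.shape
    for dz, dy, dx in offsets:
        view = padded[
            r + dz : r + dz + n[0], r + dy : r + dy + n[1], r + dx : r + dx + n[2]
        ]
        acc = view.copy() if acc is None else reduce_fn(acc, view)
    return acc


def dilate_oracle(vol, r):
    """Flat grayscale dilation: max over the ball neighbourhood."""
    return np.clip(_shift_reduce(vol, ball_offsets(r), np.maximum, 0), 0, 255).astype(np.uint8)


def erode_oracle(vol, r):
    return np.clip(_shift_reduce(vol, ball_offsets(r), np.minimum, 255), 0, 255).astype(np.uint8)


def close_oracle(vol, r):
    return erode_oracle(dilate_oracle(vol, r), r)


def threshold_oracle(vol, t):
    out = vol.copy()
    out[out < t] = 0
    return out


def fill_holes_oracle(vol):
    """Flood the border-connected background by iterated 6-neighbour spread;
    remaining zero voxels are enclosed cavities, set to their shell minimum."""
    bg = vol == 0
    reach = np.zeros_like(bg)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            reach[tuple(sl)] = bg[tuple(sl)]
    while True:
        spread = reach.copy()
        for ax in range(3):
            spread |= np.roll(reach, 1, axis=ax) & ~_edge(reach.shape, ax, 0)
            spread |= np.roll(reach, -1, axis=ax) & ~_edge(reach.shape, ax, -1)
        spread &= bg
        if (spread == reach).all():
            break
        reach = spread
    enclosed = bg & ~reach
    out = vol.copy()
    if enclosed.any():
        # label enclosed cavities by repeated flood from each unvisited voxel
        todo = enclosed.copy()
        while todo.any():
            seed = np.argwhere(todo)[0]
            comp = np.zeros_like(todo)
            comp[tuple(seed)] = True
            while True:
                grown = comp.copy()
                for ax in range(3):
                    grown |= np.roll(comp, 1, axis=ax) & ~_edge(comp.shape, ax, 0)
                    grown |= np.roll(comp, -1, axis=ax) & ~_edge(comp.shape, ax, -1)
                grown &= todo
                if (grown == comp).all():
                    break
                comp = grown
            shell_vals = []
            for ax in range(3):
                for sgn in (1, -1):
                    shifted = np.roll(comp, sgn, axis=ax)
                    shifted &= ~_edge(comp.shape, ax, 0 if sgn == 1 else -1)
                    shell_vals.append(vol[shifted & (vol > 0)])
            vals = np.concatenate(shell_vals) if shell_vals else np.array([], vol.dtype)
            out[comp] = int(vals.min()) if len(vals) else 0
            todo &= ~comp
    return out


def _edge(shape, axis, idx):
    m = np.zeros(shape, bool)
    sl = [slice(None)] * len(shape)
    sl[axis] = idx
    m[tuple(sl)] = True
    return m


def gaussian_oracle(vol, sigma, truncate=4.0):
    """Direct truncated-kernel convolution with reflect boundary."""
    r = max(1, int(truncate * sigma + 0.5))
    xs = np.arange(-r, r + 1)
    k1 = np.exp(-(xs**2) / (2 * sigma**2))
    k1 /= k1.sum()
    # edge-including reflection (numpy "symmetric"), matching the stated
    # reflect boundary of the blur definition
    padded = np.pad(vol.astype(np.float64), r, mode="symmetric")
    out = np.zeros_like(vol, dtype=np.float64)
    n = vol.shape
    for iz, wz in enumerate(k1):
        for iy, wy in enumerate(k1):
            for ix, wx in enumerate(k1):
                w = wz * wy * wx
                out += w * padded[iz : iz + n[0], iy : iy + n[1], ix : ix + n[2]]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# mesh oracles


def union_find_components(faces, n_vertices):
    """Connected components of shared-triangle vertex adjacency, by union-find."""
    parent = list(range(n_vertices))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    used = set()
    for f in faces:
        union(int(f[0]), int(f[1]))
        union(int(f[1]), int(f[2]))
        used.update(int(v) for v in f)
    labels = np.full(n_vertices, -1, int)
    roots = {}
    for v in sorted(used):
        r = find(v)
        labels[v] = roots.setdefault(r, len(roots))
    return labels


def point_triangle_distance_reference(p, a, b, c):
    """Scalar exact point-triangle distance via region classification."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(ap)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(bp)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + t * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(cp)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + t * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + t * (c - b)))
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    return np.linalg.norm(p - (a + v * ab + w * ac))


def symmetric_hausdorff_oracle(mesh_a, mesh_b):
    """All-pairs point-triangle symmetric Hausdorff for small meshes."""

    def one_way(src, dst):
        worst = 0.0
        tris = dst.vertices[dst.faces]
        for p in src.vertices:
            best = min(
                point_triangle_distance_reference(p, t[0], t[1], t[2]) for t in tris
            )
            worst = max(worst, best)
        return worst

    return max(one_way(mesh_a, mesh_b), one_way(mesh_b, mesh_a))
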