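"""Analytic test meshes: segmented tubes, shells, plates.

These primitives exist because caliber estimates need meshes with vertices
*on* the feature of interest (e.g. mid-height tube-wall vertices), which the
generic library primitives do not guarantee.  All meshes are closed and
outward-oriented.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .io import SurfaceMesh

__all__ = ["tube", "sphere", "hollow_sphere", "plate"]


def _from_trimesh(tm: trimesh.Trimesh) -> SurfaceMesh:
    if tm.volume < 0:
        tm.invert()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def tube(
    radius: float,
    height: float,
    n_theta: int = 32,
    n_z: int = 33,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SurfaceMesh:
    """Closed cylinder along z with ``n_z`` vertex rings along its height."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(-height / 2, height / 2, n_z)
    ring = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)
    verts = [
        np.column_stack([ring, np.full(n_theta, z)]) for z in zs
    ]
    verts = np.concatenate(verts)
    faces = []
    for k in range(n_z - 1):
        a = k * n_theta + np.arange(n_theta)
        b = k * n_theta + (np.arange(n_theta) + 1) % n_theta
        c, d = a + n_theta, b + n_theta
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
    # cap fans
    nv = len(verts)
    verts = np.concatenate(
        [verts, [[0, 0, -height / 2], [0, 0, height / 2]]]
    )
    bot = np.arange(n_theta)
    faces.append(np.stack([np.full(n_theta, nv), (bot + 1) % n_theta, bot], axis=1))
    top = (n_z - 1) * n_theta + np.arange(n_theta)
    top_next = (n_z - 1) * n_theta + (np.arange(n_theta) + 1) % n_theta
    faces.append(np.stack([np.full(n_theta, nv + 1), top, top_next], axis=1))
    tm = trimesh.Trimesh(verts + np.asarray(center), np.concatenate(faces), process=False)
    trimesh.repair.fix_normals(tm)
    return _from_trimesh(tm)


def sphere(
    diameter: float, subdivisions: int = 3, center: tuple[float, float, float] = (0, 0, 0)
) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=diameter / 2)
    tm.apply_translation(center)
    return _from_trimesh(tm)


def hollow_sphere(
    outer_diameter: float,
    inner_diameter: float,
    subdivisions: int = 3,
    center: tuple[float, float, float] = (0, 0, 0),
) -> SurfaceMesh:
    """Closed shell: outward outer surface plus inward-oriented inner surface."""
    outer = trimesh.creation.icosphere(subdivisions=subdivisions, radius=outer_diameter / 2)
    inner = trimesh.creation.icosphere(subdivisions=subdivisions, radius=inner_diameter / 2)
    inner.invert()
    verts = np.concatenate([outer.vertices, inner.vertices]) + np.asarray(center)
    faces = np.concatenate([outer.faces, inner.faces + len(outer.vertices)])
    return SurfaceMesh(verts, faces)


def plate(
    width: float, depth: float, thickness: float, n: int = 17,
    center: tuple[float, float, float] = (0, 0, 0),
) -> SurfaceMesh:
    """Flat box with an n×n vertex lattice on its broad faces (normal = z)."""
    xs = np.linspace(-width / 2, width / 2, n)
    ys = np.linspace(-depth / 2, depth / 2, n)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    top = np.stack([gx, gy, np.full_like(gx, thickness / 2)], axis=-1).reshape(-1, 3)
    bot = np.stack([gx, gy, np.full_like(gx, -thickness / 2)], axis=-1).reshape(-1, 3)
    verts = np.concatenate([top, bot])
    idx = np.arange(n * n).reshape(n, n)
    faces = []
    for grid, flip in ((idx, False), (idx + n * n, True)):
        a = grid[:-1, :-1].ravel()
        b = grid[1:, :-1].ravel()
        c = grid[:-1, 1:].ravel()
        d = grid[1:, 1:].ravel()
        quads = [np.stack([a, b, d], 1), np.stack([a, d, c], 1)]
        if flip:
            quads = [q[:, ::-1] for q in quads]
        faces += quads
    # side walls
    def _wall(edge_top, edge_bot, reverse=False):
        e0, e1 = edge_top[:-1], edge_top[1:]
        f0, f1 = edge_bot[:-1], edge_bot[1:]
        tris = np.concatenate(
            [np.stack([e0, f0, e1], 1), np.stack([e1, f0, f1], 1)]
        )
        return tris[:, ::-1] if reverse else tris

    faces.append(_wall(idx[0], idx[0] + n * n))
    faces.append(_wall(idx[-1], idx[-1] + n * n, reverse=True))
    faces.append(_wall(idx[:, 0], idx[:, 0] + n * n, reverse=True))
    faces.append(_wall(idx[:, -1], idx[:, -1] + n * n))
    tm = trimesh.Trimesh(verts + np.asarray(center), np.concatenate(faces), process=False)
    trimesh.repair.fix_normals(tm)
    return _from_trimesh(tm)
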