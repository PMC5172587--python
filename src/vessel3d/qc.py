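"""Semi-automatic quality control: mesh-to-mesh distances, repair, overlays.

The pipeline's solidify/smooth/filter stages can drop or distort whole
structures.  Nearest-surface distance maps in both directions between the
healed marching-cubes mesh and the final processed mesh reveal what was
lost; components of the reference mesh farther than 10 μm from the result
are appended back (repair).  A blue→red distance coloring and a
model-on-scan contour overlay support visual inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as draw_line

from .io import SectionStack, SurfaceMesh
from .analysis import ComponentSet, connected_components
from .raycast import nearest_surface_distance

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMap",
    "surface_distance",
    "colorize_distance",
    "repair_missing",
    "overlay_mesh_on_slice",
    "blind_end_census",
]


@dataclass
class DistanceMap:
    """Per-vertex nearest distance (μm) from a source mesh to a target mesh."""

    distances: np.ndarray
    direction: str  # "forward" or "backward"

    @property
    def max(self) -> float:
        return float(self.distances.max()) if len(self.distances) else 0.0

    @property
    def mean(self) -> float:
        return float(self.distances.mean()) if len(self.distances) else 0.0

    @property
    def p95(self) -> float:
        return float(np.percentile(self.distances, 95)) if len(self.distances) else 0.0

    def summary(self) -> dict[str, float]:
        return {"max": self.max, "mean": self.mean, "p95": self.p95}


def surface_distance(
    source: SurfaceMesh, target: SurfaceMesh, direction: str = "forward"
) -> DistanceMap:
    """Exact nearest-surface distance from every source vertex to the target.

    Computed as exact point-to-triangle distance (the limit of casting rays
    in all directions and keeping the shortest).  The symmetric Hausdorff
    distance is the maximum over both argument orders.
    """
    if target.is_empty:
        raise ValueError("target mesh is empty; distance undefined")
    if source.n_vertices == 0:
        return DistanceMap(np.zeros(0), direction)
    d = nearest_surface_distance(source.vertices, target.vertices, target.faces)
    source.vertex_attrs["distance_um"] = d
    return DistanceMap(d, direction)


def colorize_distance(dmap: DistanceMap, saturation: float = 10.0) -> np.ndarray:
    """Blue at zero distance, linear ramp to pure red at ≥ ``saturation`` μm."""
    if saturation <= 0:
        raise ValueError("saturation must be positive")
    t = np.clip(dmap.distances / saturation, 0, 1)[:, None]
    blue = np.array([0.0, 0.0, 255.0])
    red = np.array([255.0, 0.0, 0.0])
    return np.clip(np.rint(blue + t * (red - blue)), 0, 255).astype(np.uint8)


def repair_missing(
    reference: SurfaceMesh, processed: SurfaceMesh, threshold: float = 10.0
) -> SurfaceMesh:
    """Append reference components lying farther than ``threshold`` from the result.

    A component is "missing" when the minimum over its vertices of the
    distance to the processed mesh exceeds the threshold — the conservative
    reading that only re-adds fully lost structures.  Appended vertices are
    flagged with the ``repaired`` attribute; afterwards every reference
    component lies within ``threshold`` of the output.
    """
    comps = connected_components(reference)
    if comps.n_components == 0:
        return processed.copy()
    if processed.is_empty:
        missing = np.ones(comps.n_components, bool)
    else:
        d = nearest_surface_distance(
            reference.vertices, processed.vertices, processed.faces
        )
        cid = comps.component_id
        min_d = np.full(comps.n_components, np.inf)
        np.minimum.at(min_d, cid[cid >= 0], d[cid >= 0])
        missing = min_d > threshold
    if not missing.any():
        return processed.copy()
    add_mask = np.zeros(reference.n_vertices, bool)
    cid = comps.component_id
    add_mask[(cid >= 0) & missing[np.clip(cid, 0, None)]] = True
    addition = reference.submesh(add_mask)
    log.info("repair: re-appending %d missing components (%d vertices)",
             int(missing.sum()), addition.n_vertices)

    n0 = processed.n_vertices
    out = SurfaceMesh(
        np.concatenate([processed.vertices, addition.vertices]),
        np.concatenate([processed.faces, addition.faces + n0])
        if len(addition.faces)
        else processed.faces.copy(),
    )
    flag = np.zeros(out.n_vertices)
    flag[n0:] = 1.0
    out.vertex_attrs["repaired"] = flag
    for name, arr in processed.vertex_attrs.items():
        pad = np.zeros(addition.n_vertices, dtype=arr.dtype)
        out.vertex_attrs[name] = np.concatenate([arr, pad])
    if processed.colors is not None:
        add_col = np.full((addition.n_vertices, 3), 255, np.uint8)
        out.colors = np.concatenate([processed.colors, add_col])
    return out


def overlay_mesh_on_slice(
    mesh: SurfaceMesh,
    stack: SectionStack,
    slice_index: int,
    view_tilt: float = 0.0,
    color: tuple[int, int, int] = (0, 220, 0),
) -> np.ndarray:
    """Draw the mesh's cross-section contour onto a registered scan slice.

    The mesh is cut by the plane of section ``slice_index`` (optionally
    tilted by ``view_tilt`` radians about the x axis through the plane
    centre, which gives a quasi-3D impression over the 2D scan); the
    intersection segments are rasterised as an outline.  Fully deterministic.
    """
    if not 0 <= slice_index < stack.n_slices:
        raise IndexError("slice_index out of range")
    img = stack.slices[slice_index].copy()
    if mesh.is_empty:
        return img
    z0 = slice_index * stack.z_spacing
    h, w = stack.shape
    centre = np.array([w * stack.xy_spacing / 2, h * stack.xy_spacing / 2, z0])

    verts = mesh.vertices - centre
    if view_tilt:
        c, s = np.cos(view_tilt), np.sin(view_tilt)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
        verts = verts @ rot.T
    zs = verts[:, 2]
    tri_z = zs[mesh.faces]
    crossing = (tri_z.min(axis=1) <= 0) & (tri_z.max(axis=1) >= 0)
    for f in mesh.faces[crossing]:
        pts = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            za, zb = zs[f[a]], zs[f[b]]
            if (za <= 0 <= zb) or (zb <= 0 <= za):
                t = za / (za - zb) if za != zb else 0.0
                pts.append(verts[f[a]] + t * (verts[f[b]] - verts[f[a]]))
            if len(pts) == 2:
                break
        if len(pts) == 2:
            p0 = (pts[0][:2] + centre[:2]) / stack.xy_spacing
            p1 = (pts[1][:2] + centre[:2]) / stack.xy_spacing
            r0, c0 = int(round(p0[1])), int(round(p0[0]))
            r1, c1 = int(round(p1[1])), int(round(p1[0]))
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            img[rr[ok], cc[ok]] = color
    return img


def blind_end_census(
    mesh: SurfaceMesh,
    comps: ComponentSet,
    bbox: np.ndarray,
    tol: float = 1.0,
    geodesic_radius: float = 15.0,
) -> dict:
    """Heuristic census of candidate blind vessel ends for manual review.

    For every component the two geodesic extremities (double-BFS poles) are
    examined: a pole is a candidate blind end when it does not lie on the
    stack boundary and the geodesic ring at ``geodesic_radius`` around it
    stays compact (a tube cap), as opposed to the wide ring a pole on a
    closed loop or broad surface produces.  A component touching two or more
    bounding-box faces with no such pole reports zero blind ends.  Reviewing
    aid only.
    """
    bbox = np.asarray(bbox, float).reshape(2, 3)
    report = {"components": [], "total_blind_ends": 0}
    if mesh.is_empty or comps.n_components == 0:
        return report
    from scipy.sparse.csgraph import dijkstra
    from scipy import sparse as sp

    e = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    wts = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    adj = sp.csr_matrix((wts, (e[:, 0], e[:, 1])), shape=(n, n))
    adj = adj.maximum(adj.T)

    near_face = (
        (np.abs(mesh.vertices - bbox[0]) <= tol)
        | (np.abs(mesh.vertices - bbox[1]) <= tol)
    )
    faces_touched_per_vertex = near_face.any(axis=1)

    for c in range(comps.n_components):
        sel = np.flatnonzero(comps.component_id == c)
        touched = set()
        for ax in range(3):
            if (np.abs(mesh.vertices[sel, ax] - bbox[0, ax]) <= tol).any():
                touched.add(("min", ax))
            if (np.abs(mesh.vertices[sel, ax] - bbox[1, ax]) <= tol).any():
                touched.add(("max", ax))
        blind = 0
        # double BFS: farthest point from an arbitrary seed, then farthest from it
        d0 = dijkstra(adj, indices=sel[0], directed=False)
        d0[~np.isfinite(d0)] = -1
        pole_a = int(np.argmax(np.where(comps.component_id == c, d0, -1)))
        da = dijkstra(adj, indices=pole_a, directed=False)
        da_m = np.where(comps.component_id == c, da, -1)
        pole_b = int(np.argmax(da_m))
        db = dijkstra(adj, indices=pole_b, directed=False)
        for pole, dist in ((pole_a, da), (pole_b, db)):
            if faces_touched_per_vertex[pole]:
                continue
            ring = sel[
                (dist[sel] >= geodesic_radius) & (dist[sel] <= geodesic_radius * 1.3)
            ]
            if len(ring) == 0:
                continue  # component smaller than the probe radius
            ring_diam = 0.0
            if len(ring) > 1:
                p = mesh.vertices[ring]
                ring_diam = float(
                    np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1).max()
                )
            if ring_diam < 1.2 * geodesic_radius:
                blind += 1
        report["components"].append(
            {"component": c, "bbox_faces_touched": len(touched), "blind_ends": blind}
        )
        report["total_blind_ends"] += blind
    return report
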