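"""Synthetic stained-section phantoms with known microvessel ground truth.

Bone-marrow microvessels come in two caliber classes that form largely
disjoint networks: thin capillaries (≈2–12 μm, in predominantly adipose
areas) and wide, often flattened sinuses (≥30 μm, draining haematopoietic
areas), with only sparse end-to-side anastomoses between the classes.  The
generator grows one random space-filling tree per network inside its own
spatial slab, renders the stained endothelial *walls* as brown DAB-like
tubes on a light background, samples one section every ``z_spacing`` μm,
and can inject the classic sectioning artefacts: unstained wall gaps,
collapsed capillaries and isolated stained cells.

Every operation is deterministic given the spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io import ScalarVolume, SectionStack

log = logging.getLogger(__name__)

__all__ = [
    "DefectRates",
    "PhantomSpec",
    "PhantomTruth",
    "RecoveryReport",
    "generate_network",
    "rasterize_truth",
    "render_sections",
    "evaluate_recovery",
]

STAIN_RGB = np.array([120, 70, 20], float)       # DAB brown, HSV saturation ≈ 212
BACKGROUND_RGB = np.array([235, 230, 225], float)  # near-achromatic, saturation ≈ 11


@dataclass
class DefectRates:
    wall_gap_per_100um: float = 0.5
    collapse_fraction: float = 0.1
    isolated_cells_per_mm3: float = 2000.0


@dataclass
class PhantomSpec:
    """Geometry and artefact parameters of one synthetic specimen."""

    domain_size: tuple[float, float, float] = (200.0, 200.0, 140.0)  # μm (x, y, z)
    n_capillary_networks: int = 1
    n_sinus_networks: int = 2
    capillary_diam_range: tuple[float, float] = (2.0, 12.0)
    sinus_diam_range: tuple[float, float] = (30.0, 60.0)
    n_cross_connections: int = 0
    wall_thickness: float = 1.5
    sinus_flatness_max: float = 3.0   # up to 3:1 elliptical flattening along z
    step_um: float = 10.0             # random-walk growth step
    branch_prob: float = 0.15
    z_bias: float = 0.4               # growth bias along z (vessels traverse the stack)
    min_separation: float = 25.0      # surface-to-surface margin between networks
    defect_rates: DefectRates = field(default_factory=DefectRates)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.defect_rates, dict):
            self.defect_rates = DefectRates(**self.defect_rates)
        if any(s <= 0 for s in self.domain_size):
            raise ValueError("domain_size must be positive")
        for rng_ in (self.capillary_diam_range, self.sinus_diam_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError("diameter ranges must be positive and ordered")
        if self.capillary_diam_range[1] >= self.sinus_diam_range[0]:
            raise ValueError("capillary and sinus diameter ranges must not overlap")


@dataclass
class PhantomTruth:
    """Ground-truth centerline graph plus isolated stained cells.

    Graph nodes carry ``pos`` (x, y, z μm); edges carry ``diameter`` μm,
    ``vessel_class`` ∈ {capillary, sinus}, ``network_id`` and ``flatness``
    (z-flattening ratio, 1 = round).
    """

    graph: nx.Graph
    cells: list[tuple[np.ndarray, float]]
    spec: PhantomSpec

    @property
    def n_networks(self) -> int:
        ids = {d["network_id"] for _, _, d in self.graph.edges(data=True)}
        return len(ids)

    def edge_segments(self):
        """Yield (p0, p1, diameter, vessel_class, network_id, flatness) per edge."""
        pos = nx.get_node_attributes(self.graph, "pos")
        for u, v, d in self.graph.edges(data=True):
            yield (
                np.asarray(pos[u], float),
                np.asarray(pos[v], float),
                d["diameter"],
                d["vessel_class"],
                d["network_id"],
                d.get("flatness", 1.0),
            )


@dataclass
class RecoveryReport:
    n_true_networks: int
    n_found_networks: int
    vertex_class_accuracy: float
    component_diameter_errors: list[float]
    topology_match: bool

    def __post_init__(self) -> None:
        if not 0 <= self.vertex_class_accuracy <= 1:
            raise ValueError("accuracy must be a fraction")


# ---------------------------------------------------------------------------
# network growth


def _grow_tree(
    rng: np.random.Generator,
    lo: np.ndarray,
    hi: np.ndarray,
    start: np.ndarray,
    step: float,
    branch_prob: float,
    z_bias: float,
    n_steps: int,
    other_points: np.ndarray | None,
    other_radii: np.ndarray | None,
    self_radius: float,
    min_separation: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Biased random-walk tree inside [lo, hi]; returns list of segments."""
    other_tree = cKDTree(other_points) if other_points is not None and len(other_points) else None
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    d0 = rng.normal(size=3)
    d0[2] = abs(d0[2]) + z_bias * 2
    frontier = [(start, d0 / np.linalg.norm(d0))]
    steps_used = 0
    while frontier and steps_used < n_steps:
        pos, direction = frontier.pop(0)
        for _ in range(30):  # one branch segment chain
            if steps_used >= n_steps:
                break
            new_dir = direction + 0.45 * rng.normal(size=3)
            new_dir[2] += z_bias * rng.uniform(0.0, 1.0) * np.sign(new_dir[2] or 1.0)
            # steer back toward the slab centre near the walls
            centre_pull = ((lo + hi) / 2 - pos) / np.maximum(hi - lo, 1e-9)
            edge_prox = np.clip(1.0 - 2 * np.minimum(pos - lo, hi - pos) / (hi - lo), 0, 1)
            new_dir += 1.5 * edge_prox * centre_pull
            norm = np.linalg.norm(new_dir)
            if norm < 1e-9:
                continue
            new_dir /= norm
            nxt = pos + step * new_dir
            if (nxt < lo).any() or (nxt > hi).any():
                direction = direction * np.where(
                    (nxt < lo) | (nxt > hi), -1.0, 1.0
                )
                continue
            if other_tree is not None:
                dist, idx = other_tree.query(nxt, k=1)
                # surface-to-surface clearance against the nearest foreign tube
                if dist < self_radius + other_radii[idx] + min_separation:
                    break  # keep networks mutually exclusive
            segments.append((pos, nxt))
            steps_used += 1
            if rng.random() < branch_prob:
                frontier.append((nxt, new_dir + 0.8 * rng.normal(size=3)))
            pos, direction = nxt, new_dir
    return segments


def generate_network(spec: PhantomSpec) -> PhantomTruth:
    """Grow the requested capillary and sinus networks plus anastomoses.

    Networks of the two classes occupy disjoint slabs of the domain
    (capillaries in the adipose-like band, sinuses in the haematopoietic
    band) and are grown as seeded random trees; ``n_cross_connections``
    end-to-side links are added afterwards between nearest node pairs.
    """
    rng = np.random.default_rng(spec.seed)
    size = np.asarray(spec.domain_size, float)
    n_nets = spec.n_capillary_networks + spec.n_sinus_networks
    if n_nets < 1:
        raise ValueError("need at least one network")

    # one x-slab per network, capillaries first; width proportional to caliber
    # plus the separation each slab must buy on both sides
    weights = [spec.capillary_diam_range[1]] * spec.n_capillary_networks + [
        spec.sinus_diam_range[1]
    ] * spec.n_sinus_networks
    weights = np.asarray(weights, float) + 2 * spec.min_separation
    edges_x = np.concatenate([[0.0], np.cumsum(weights) / weights.sum() * size[0]])

    graph = nx.Graph()
    node_id = 0
    all_points: list[np.ndarray] = []
    all_radii: list[float] = []
    classes = ["capillary"] * spec.n_capillary_networks + ["sinus"] * spec.n_sinus_networks
    for net_id, vclass in enumerate(classes):
        if vclass == "capillary":
            lo_d, hi_d = spec.capillary_diam_range
        else:
            lo_d, hi_d = spec.sinus_diam_range
        # a single vascular bed has a characteristic caliber: sample the
        # network's base diameter from the central part of its class range
        base = rng.uniform(lo_d + 0.2 * (hi_d - lo_d), lo_d + 0.5 * (hi_d - lo_d))
        flatness = 1.0
        if vclass == "sinus" and spec.sinus_flatness_max > 1.0:
            flatness = rng.uniform(1.0, spec.sinus_flatness_max)
        r = base / 2
        margin = r + max(spec.wall_thickness + 1.0, spec.min_separation / 2)
        lo = np.array([edges_x[net_id], 0.0, 0.0]) + margin
        hi = np.array([edges_x[net_id + 1], size[1], size[2]]) - margin
        if (hi <= lo).any():
            raise ValueError(
                f"domain too small for network {net_id} ({vclass}, diameter {base:.1f} μm)"
            )
        start = lo + rng.uniform(0.15, 0.45, size=3) * (hi - lo)
        budget = max(12, int(1.2 * size[2] / spec.step_um) + 8)
        segs = _grow_tree(
            rng, lo, hi, start, spec.step_um, spec.branch_prob, spec.z_bias,
            budget, np.asarray(all_points) if all_points else None,
            np.asarray(all_radii) if all_radii else None,
            self_radius=r, min_separation=spec.min_separation,
        )
        if not segs:
            raise ValueError(f"could not grow network {net_id} in its subdomain")
        pos2id: dict[bytes, int] = {}
        for p0, p1 in segs:
            ids = []
            for p in (p0, p1):
                key = p.tobytes()
                if key not in pos2id:
                    pos2id[key] = node_id
                    graph.add_node(node_id, pos=p.copy())
                    node_id += 1
                    all_points.append(p.copy())
                    all_radii.append(r)
                ids.append(pos2id[key])
            diam = float(np.clip(base * rng.uniform(0.9, 1.1), lo_d, hi_d))
            graph.add_edge(
                ids[0], ids[1], diameter=diam, vessel_class=vclass,
                network_id=net_id, flatness=flatness,
            )

    # sparse end-to-side anastomoses: capillary → sinus, abrupt caliber change
    cap_nodes = [
        n for n in graph.nodes
        if any(d["vessel_class"] == "capillary" for d in graph[n].values())
    ]
    sin_nodes = [
        n for n in graph.nodes
        if any(d["vessel_class"] == "sinus" for d in graph[n].values())
    ]
    for c in range(spec.n_cross_connections):
        if not cap_nodes or not sin_nodes:
            raise ValueError("cross connections need both vessel classes")
        cap = cap_nodes[rng.integers(len(cap_nodes))]
        pos = nx.get_node_attributes(graph, "pos")
        dists = [np.linalg.norm(pos[s] - pos[cap]) for s in sin_nodes]
        sin = sin_nodes[int(np.argmin(dists))]
        cap_net = next(iter(graph[cap].values()))["network_id"]
        diam = float(np.mean(spec.capillary_diam_range))
        graph.add_edge(cap, sin, diameter=diam, vessel_class="capillary",
                       network_id=cap_net, flatness=1.0)

    # isolated stained cells
    vol_mm3 = float(np.prod(size)) * 1e-9
    n_cells = int(round(spec.defect_rates.isolated_cells_per_mm3 * vol_mm3))
    cells = [
        (rng.uniform(5.0, size - 5.0), float(rng.uniform(6.0, 10.0)))
        for _ in range(n_cells)
    ]
    log.info("phantom: %d networks, %d nodes, %d edges, %d cells",
             n_nets, graph.number_of_nodes(), graph.number_of_edges(), len(cells))
    return PhantomTruth(graph, cells, spec)


# ---------------------------------------------------------------------------
# rasterization


def _paint_edge_plane(
    mask: np.ndarray,
    z_um: float | np.ndarray,
    yy: np.ndarray,
    xx: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    outer_r: float,
    inner_r: float,
    flatness: float,
) -> None:
    """Mark the wall shell of one tube segment on a 2-D plane (or 3-D grid)."""
    zz = np.broadcast_to(np.asarray(z_um, float), xx.shape)
    p = np.stack([xx, yy, zz], axis=-1)
    seg = p1 - p0
    L2 = float(seg @ seg)
    t = np.clip(((p - p0) @ seg) / max(L2, 1e-12), 0.0, 1.0)
    diff = p - (p0 + t[..., None] * seg)
    if flatness != 1.0:
        diff = diff.copy()
        diff[..., 2] *= flatness  # elliptical cross-section squeezed along z
    dist = np.linalg.norm(diff, axis=-1)
    mask |= (dist <= outer_r) & (dist >= inner_r)


def _paint_sphere_plane(
    mask: np.ndarray, z_um, yy, xx, centre: np.ndarray, radius: float
) -> None:
    zz = np.broadcast_to(np.asarray(z_um, float), xx.shape)
    d2 = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (zz - centre[2]) ** 2
    mask |= d2 <= radius**2


def rasterize_truth(
    truth: PhantomTruth, spacing: tuple[float, float, float]
) -> ScalarVolume:
    """Binary occupancy (255) of the vessel-wall shells and cells on a voxel grid."""
    sz, sy, sx = (float(s) for s in spacing)
    if min(sz, sy, sx) <= 0:
        raise ValueError("spacing must be positive")
    size = np.asarray(truth.spec.domain_size, float)
    nz = int(np.floor(size[2] / sz)) + 1  # inclusive z planes (140/7 -> 21)
    ny = int(round(size[1] / sy))
    nx_ = int(round(size[0] / sx))
    mask = np.zeros((nz, ny, nx_), bool)
    wall = truth.spec.wall_thickness
    y_um, x_um = np.meshgrid(np.arange(ny) * sy, np.arange(nx_) * sx, indexing="ij")
    for k in range(nz):
        z = k * sz
        plane = mask[k]
        for p0, p1, diam, _, _, flat in truth.edge_segments():
            if z < min(p0[2], p1[2]) - diam or z > max(p0[2], p1[2]) + diam:
                continue
            outer = diam / 2
            _paint_edge_plane(plane, z, y_um, x_um, p0, p1, outer,
                              max(outer - wall, 0.0), flat)
        for centre, cdiam in truth.cells:
            if abs(z - centre[2]) <= cdiam / 2:
                _paint_sphere_plane(plane, z, y_um, x_um, centre, cdiam / 2)
    return ScalarVolume(mask.astype(np.uint8) * 255, (sz, sy, sx), provenance="truth")


def render_sections(
    truth: PhantomTruth,
    spec: PhantomSpec | None = None,
    xy_spacing: float = 0.55,
    z_spacing: float = 7.0,
) -> SectionStack:
    """Render the truth as brown-on-light serial sections with injected defects.

    Sections are sampled inclusively every ``z_spacing`` μm (a 140 μm domain
    at 7 μm yields 21 sections).  Defects applied at the spec's rates:
    unstained wall gaps, capillaries collapsed to a ≈2.5 μm solid profile,
    and the truth's isolated stained cells.  Byte-identical across runs for
    a fixed seed.
    """
    spec = spec or truth.spec
    if z_spacing < xy_spacing:
        raise ValueError("z_spacing must be >= xy_spacing (anisotropic stacks)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    size = np.asarray(spec.domain_size, float)
    n_slices = int(np.floor(size[2] / z_spacing)) + 1  # inclusive endpoints
    ny = int(round(size[1] / xy_spacing))
    nx_ = int(round(size[0] / xy_spacing))
    y_um, x_um = np.meshgrid(
        np.arange(ny) * xy_spacing, np.arange(nx_) * xy_spacing, indexing="ij"
    )
    wall = spec.wall_thickness

    edges = list(truth.edge_segments())
    collapsed = rng.random(len(edges)) < (
        spec.defect_rates.collapse_fraction if spec.defect_rates else 0.0
    )
    # pre-draw wall-gap centres on each edge's surface (deterministic)
    gap_centres: list[np.ndarray] = []
    gap_radius = 2.5
    for idx, (p0, p1, diam, vclass, _, flat) in enumerate(edges):
        length = np.linalg.norm(p1 - p0)
        lam = spec.defect_rates.wall_gap_per_100um * length / 100.0
        for _ in range(rng.poisson(lam)):
            t = rng.uniform()
            axis_pt = p0 + t * (p1 - p0)
            phi = rng.uniform(0, 2 * np.pi)
            seg = (p1 - p0) / max(length, 1e-9)
            ref = np.array([1.0, 0, 0]) if abs(seg[0]) < 0.9 else np.array([0, 1.0, 0])
            u = np.cross(seg, ref)
            u /= np.linalg.norm(u)
            v = np.cross(seg, u)
            gap_centres.append(axis_pt + (diam / 2) * (np.cos(phi) * u + np.sin(phi) * v))
    gap_centres_arr = np.asarray(gap_centres) if gap_centres else np.empty((0, 3))

    slices = []
    for k in range(n_slices):
        z = k * z_spacing
        stained = np.zeros((ny, nx_), bool)
        for idx, (p0, p1, diam, vclass, _, flat) in enumerate(edges):
            outer = diam / 2
            inner = max(outer - wall, 0.0)
            if collapsed[idx] and vclass == "capillary":
                outer, inner, flat = 1.25, 0.0, 1.0  # squeezed to ~2.5 μm solid
            if z < min(p0[2], p1[2]) - diam or z > max(p0[2], p1[2]) + diam:
                continue
            _paint_edge_plane(stained, z, y_um, x_um, p0, p1, outer, inner, flat)
        for centre, cdiam in truth.cells:
            if abs(z - centre[2]) <= cdiam / 2:
                _paint_sphere_plane(stained, z, y_um, x_um, centre, cdiam / 2)
        # punch unstained wall gaps
        for g in gap_centres_arr:
            if abs(g[2] - z) <= gap_radius:
                r2 = gap_radius**2 - (g[2] - z) ** 2
                stained &= (x_um - g[0]) ** 2 + (y_um - g[1]) ** 2 > r2
        img = np.where(
            stained[..., None],
            STAIN_RGB + rng.normal(0, 6, (ny, nx_, 3)),
            BACKGROUND_RGB + rng.normal(0, 3, (ny, nx_, 3)),
        )
        slices.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return SectionStack(slices, xy_spacing, z_spacing)


# ---------------------------------------------------------------------------
# truth graph (de)serialisation


def truth_to_json(truth: PhantomTruth) -> dict:
    """JSON-ready dict of the truth graph (nodes, edges, diameters, cells)."""
    pos = nx.get_node_attributes(truth.graph, "pos")
    return {
        "domain_size": list(truth.spec.domain_size),
        "seed": truth.spec.seed,
        "nodes": [{"id": int(n), "pos": list(map(float, pos[n]))} for n in truth.graph.nodes],
        "edges": [
            {
                "u": int(u), "v": int(v),
                "diameter": float(d["diameter"]),
                "vessel_class": d["vessel_class"],
                "network_id": int(d["network_id"]),
                "flatness": float(d.get("flatness", 1.0)),
            }
            for u, v, d in truth.graph.edges(data=True)
        ],
        "cells": [
            {"pos": list(map(float, c)), "diameter": float(diam)}
            for c, diam in truth.cells
        ],
    }


def truth_from_json(payload: dict, spec: PhantomSpec | None = None) -> PhantomTruth:
    spec = spec or PhantomSpec(
        domain_size=tuple(payload["domain_size"]), seed=payload.get("seed", 0)
    )
    g = nx.Graph()
    for n in payload["nodes"]:
        g.add_node(int(n["id"]), pos=np.asarray(n["pos"], float))
    for e in payload["edges"]:
        g.add_edge(
            int(e["u"]), int(e["v"]), diameter=e["diameter"],
            vessel_class=e["vessel_class"], network_id=e["network_id"],
            flatness=e.get("flatness", 1.0),
        )
    cells = [(np.asarray(c["pos"], float), c["diameter"]) for c in payload["cells"]]
    return PhantomTruth(g, cells, spec)


# ---------------------------------------------------------------------------
# recovery evaluation


def _truth_samples(truth: PhantomTruth, ds: float = 2.0, exclude_flat: float | None = None):
    pts, classes, nets, diams = [], [], [], []
    for p0, p1, diam, vclass, net, flat in truth.edge_segments():
        if exclude_flat is not None and flat >= exclude_flat:
            continue
        length = np.linalg.norm(p1 - p0)
        n = max(2, int(length / ds) + 1)
        t = np.linspace(0, 1, n)
        pts.append(p0 + t[:, None] * (p1 - p0))
        classes += [vclass] * n
        nets += [net] * n
        diams += [diam] * n
    if not pts:
        return np.empty((0, 3)), np.array([]), np.array([]), np.array([])
    return (
        np.concatenate(pts),
        np.asarray(classes),
        np.asarray(nets),
        np.asarray(diams),
    )


def evaluate_recovery(
    truth: PhantomTruth,
    mesh,
    component_ids: np.ndarray,
    sdf_um: np.ndarray,
    sdf_center: float = 16.5,
    exclude_flat_sinuses: float | None = 1.5,
) -> RecoveryReport:
    """Score a reconstructed, SDF-attributed mesh against the ground truth.

    Class accuracy is the fraction of valid-SDF vertices whose caliber class
    (capillary if SDF < ``sdf_center``, else sinus) matches the class of the
    nearest truth centerline point.  Sinus edges flattened beyond
    ``exclude_flat_sinuses`` are exempted (a flat sinus legitimately reads
    thin from its broad side).  Components are matched to truth networks by
    the majority network of their vertices' nearest centerline points.
    """
    n_true = truth.n_networks
    if mesh is None or mesh.is_empty:
        return RecoveryReport(n_true, 0, 0.0, [], False)
    pts, classes, nets, diams = _truth_samples(truth)
    if len(pts) == 0:
        return RecoveryReport(0, 0, 0.0, [], False)
    tree = cKDTree(pts)
    _, nearest = tree.query(mesh.vertices, k=1)

    valid = np.isfinite(np.asarray(sdf_um, float))
    pred_cap = np.asarray(sdf_um, float) < sdf_center
    true_cap = classes[nearest] == "capillary"
    scored = valid.copy()
    if exclude_flat_sinuses is not None:
        pts_nf, *_ = _truth_samples(truth, exclude_flat=exclude_flat_sinuses)
        if len(pts_nf) and len(pts_nf) != len(pts):
            keep_tree = cKDTree(pts_nf)
            d_nf, _ = keep_tree.query(pts[nearest], k=1)
            scored &= d_nf < 1e-6  # vertex maps to a non-exempted edge sample
    accuracy = float((pred_cap == true_cap)[scored].mean()) if scored.any() else 0.0

    component_ids = np.asarray(component_ids)
    found = np.unique(component_ids[component_ids >= 0])
    comp_to_net = {}
    diam_errors = []
    for cid in found:
        sel = component_ids == cid
        net_votes = nets[nearest[sel]]
        maj = np.bincount(net_votes.astype(int)).argmax()
        comp_to_net[int(cid)] = int(maj)
        sdf_sel = np.asarray(sdf_um, float)[sel & valid]
        if len(sdf_sel):
            diam_errors.append(float(np.median(sdf_sel) - diams[nearest[sel]].mean()))
    topology = (len(found) == n_true) and (
        len(set(comp_to_net.values())) == n_true
    )
    return RecoveryReport(n_true, int(len(found)), accuracy, diam_errors, bool(topology))
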