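"""End-to-end orchestration of the reconstruction pipeline.

Stages, in order: HSV-saturation extraction → optical-flow z-interpolation →
six-filter segmentation → marching-cubes isosurface → heal/solidify → Taubin
smoothing, then two analysis branches (caliber/SDF model and connectivity
model) plus the QC block (bidirectional surface distances, 10 μm repair,
stage-difference panels).  A manifest of the config hash and per-stage
checksums makes runs reproducible and comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from skimage.measure import block_reduce

from . import analysis, colorflow, filters, meshing, qc
from .io import (
    PipelineConfig,
    ScalarVolume,
    SectionStack,
    SurfaceMesh,
    write_mesh,
    write_volume,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    saturation: ScalarVolume
    interpolated: ScalarVolume
    filtered: ScalarVolume
    reference_mesh: SurfaceMesh          # healed marching-cubes mesh (QC reference)
    smoothed_mesh: SurfaceMesh
    sdf_mesh: SurfaceMesh                # caliber model (branch A)
    sdf_field: analysis.SdfField | None
    sdf_components: analysis.ComponentSet | None
    connectivity_mesh: SurfaceMesh       # connectivity model (branch B)
    connectivity_classes: dict[int, str]
    connectivity_components: analysis.ComponentSet | None
    distance_forward: qc.DistanceMap | None
    distance_backward: qc.DistanceMap | None
    repaired_mesh: SurfaceMesh | None
    stage_panels: list[np.ndarray]
    manifest: dict = field(default_factory=dict)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _downsample_xy(vol: ScalarVolume, factor: int) -> ScalarVolume:
    if factor == 1:
        return vol
    data = block_reduce(vol.data, (1, factor, factor), np.mean)
    data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    sz, sy, sx = vol.spacing
    return ScalarVolume(data, (sz, sy * factor, sx * factor), vol.provenance)


def run_pipeline(
    config: PipelineConfig,
    stack: SectionStack,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full reconstruction on a registered section stack.

    Raises ``ValueError`` with a stage label if a stage's preconditions fail
    (e.g. a single-slice stack cannot be interpolated).  When ``outdir`` is
    given, volumes, meshes and the manifest are written there.
    """
    manifest: dict = {"config_hash": _config_hash(config), "stages": {}, "timings_s": {}}

    def _stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
        manifest["timings_s"][name] = round(time.time() - t0, 3)
        return out

    sat = _stage("saturation", lambda: colorflow.extract_saturation(stack))
    sat = _downsample_xy(sat, config.downsample_xy)
    manifest["stages"]["saturation"] = _checksum(sat.data)

    interp = _stage(
        "interpolate",
        lambda: colorflow.interpolate_slices(
            sat, config.interp_target_z, config.flow_radius, config.flow_num_warp
        ),
    )
    manifest["stages"]["interpolate"] = _checksum(interp.data)

    filtered = _stage("filter", lambda: filters.apply_chain(interp, config.filter_chain))
    manifest["stages"]["filter"] = _checksum(filtered.data)

    raw_mesh = _stage(
        "isosurface", lambda: meshing.extract_isosurface(filtered, config.iso_value)
    )
    reference = _stage("heal", lambda: meshing.heal_and_solidify(raw_mesh))
    manifest["stages"]["heal"] = _checksum(reference.vertices)
    smoothed = _stage(
        "taubin",
        lambda: meshing.taubin_smooth(
            reference, config.taubin_iters, config.taubin_lam, config.taubin_mu
        ),
    )
    manifest["stages"]["taubin"] = _checksum(smoothed.vertices)

    bbox = filtered.world_bounds()
    meshing.label_cut_surface(smoothed, bbox)

    # ---- branch A: caliber (SDF) model
    sdf_mesh = SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), int))
    sdf_field = None
    sdf_comps = None
    if not smoothed.is_empty:
        obsc = _stage(
            "obscurance",
            lambda: analysis.volumetric_obscurance(smoothed, config.obscurance_n_samples),
        )
        interior_removed = _stage(
            "remove_interior",
            lambda: analysis.remove_interior(smoothed, obsc, config.obscurance_threshold),
        )
        comps_a = _stage("components_a", lambda: analysis.connected_components(interior_removed))
        sdf_mesh = _stage(
            "filter_components",
            lambda: analysis.filter_components(
                interior_removed, comps_a, config.component_min_diam
            ),
        )
        if not sdf_mesh.is_empty:
            sdf_field = _stage(
                "sdf",
                lambda: analysis.shape_diameter(
                    sdf_mesh,
                    np.deg2rad(config.sdf_cone_half_angle_deg),
                    config.sdf_n_rays,
                ),
            )
            sdf_mesh.colors = analysis.colorize_sdf(
                sdf_field, config.sdf_low, config.sdf_high, config.sdf_center
            )
            cut = meshing.label_cut_surface(sdf_mesh, bbox)
            sdf_mesh.colors[cut] = (200, 200, 200)  # light grey cut surfaces
            sdf_comps = analysis.connected_components(sdf_mesh)
    manifest["stages"]["sdf_mesh"] = _checksum(sdf_mesh.vertices)

    # ---- branch B: connectivity model
    conn_mesh = SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), int))
    conn_classes: dict[int, str] = {}
    conn_comps = None
    if not smoothed.is_empty:
        comps_b = _stage("components_b", lambda: analysis.connected_components(smoothed))
        conn_mesh, _, conn_classes = _stage(
            "connectivity",
            lambda: analysis.classify_connectivity(
                smoothed, comps_b, config.small_min, config.small_max,
                config.n_large_networks,
            ),
        )
        cut = meshing.label_cut_surface(conn_mesh, bbox)
        if conn_mesh.colors is not None and len(conn_mesh.colors):
            conn_mesh.colors[cut] = (160, 200, 255)  # light blue cut surfaces
        conn_comps = analysis.connected_components(conn_mesh)
    manifest["stages"]["connectivity_mesh"] = _checksum(conn_mesh.vertices)

    # ---- QC block
    fwd = bwd = None
    repaired = None
    if not reference.is_empty and not sdf_mesh.is_empty:
        fwd = _stage("hausdorff_fwd", lambda: qc.surface_distance(reference, sdf_mesh, "forward"))
        bwd = _stage("hausdorff_bwd", lambda: qc.surface_distance(sdf_mesh, reference, "backward"))
        repaired = _stage(
            "repair",
            lambda: qc.repair_missing(reference, sdf_mesh, config.hausdorff_repair),
        )
        manifest["stages"]["repaired"] = _checksum(repaired.vertices)
        manifest["qc"] = {
            "forward": fwd.summary(),
            "backward": bwd.summary(),
            "symmetric_hausdorff_um": max(fwd.max, bwd.max),
        }
    panels = _stage(
        "stage_report",
        lambda: filters.stage_difference_report(interp, filtered, stack=stack, saturation=sat),
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_volume(sat, outdir / "saturation.tif")
        write_volume(interp, outdir / "interpolated.tif")
        write_volume(filtered, outdir / "filtered.tif")
        for name, mesh in (
            ("reference.ply", reference),
            ("smoothed.ply", smoothed),
            ("model_sdf.ply", sdf_mesh),
            ("model_connectivity.ply", conn_mesh),
        ):
            if not mesh.is_empty:
                write_mesh(mesh, outdir / name)
        if repaired is not None and not repaired.is_empty:
            write_mesh(repaired, outdir / "repaired.ply")
        import imageio.v3 as iio

        for i, panel in enumerate(panels):
            iio.imwrite(outdir / f"qc_stages_{i:02d}.png", panel)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        saturation=sat,
        interpolated=interp,
        filtered=filtered,
        reference_mesh=reference,
        smoothed_mesh=smoothed,
        sdf_mesh=sdf_mesh,
        sdf_field=sdf_field,
        sdf_components=sdf_comps,
        connectivity_mesh=conn_mesh,
        connectivity_classes=conn_classes,
        connectivity_components=conn_comps,
        distance_forward=fwd,
        distance_backward=bwd,
        repaired_mesh=repaired,
        stage_panels=panels,
        manifest=manifest,
    )
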