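"""RGB → stain-saturation conversion and optical-flow z-interpolation.

Serial sections are sampled far more finely in-plane (0.28 μm/px) than along
z (7 μm/section).  Working on the HSV saturation channel — bright where the
brown DAB reaction product is, dark on unstained background — the stack is
resampled along z by estimating a dense optical-flow field between each pair
of consecutive sections and generating flow-warped intermediate planes, e.g.
21 sections at 7 μm become 140 planes at 1 μm.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import optical_flow_ilk

from .io import ScalarVolume, SectionStack

log = logging.getLogger(__name__)

__all__ = ["extract_saturation", "interpolate_slices"]


def extract_saturation(stack: SectionStack, scale: int = 255) -> ScalarVolume:
    """Convert an RGB stack to its HSV saturation channel, scaled to 0–255.

    S = (max(R,G,B) − min(R,G,B)) / max(R,G,B), with S = 0 where max = 0.
    Brown-stained endothelium is strongly saturated (bright); the nearly
    achromatic background is dark.
    """
    arr = stack.as_array().astype(np.float32)  # (z, y, x, 3)
    mx = arr.max(axis=-1)
    mn = arr.min(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(mx > 0, (mx - mn) / mx, 0.0)
    data = np.clip(np.rint(sat * scale), 0, 255).astype(np.uint8)
    return ScalarVolume(
        data,
        spacing=(stack.z_spacing, stack.xy_spacing, stack.xy_spacing),
        provenance="saturation",
    )


def _warp(img: np.ndarray, flow: np.ndarray, t: float) -> np.ndarray:
    """Warp ``img`` along ``t`` times the flow field (bilinear, range-preserving)."""
    ny, nx = img.shape
    grid_y, grid_x = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    coords = np.stack([grid_y + t * flow[0], grid_x + t * flow[1]])
    return ndi.map_coordinates(img, coords, order=1, mode="nearest")


def interpolate_slices(
    vol: ScalarVolume,
    target_z: float,
    flow_radius: int = 10,
    flow_num_warp: int = 3,
) -> ScalarVolume:
    """Resample a coarse-z volume to ``target_z`` μm using dense optical flow.

    For each of the n−1 gaps between consecutive planes a dense flow field is
    estimated in both directions and ``m = z_spacing / target_z`` planes are
    emitted: the leading original plus m−1 symmetric, bidirectionally warped
    blends.  The trailing original of the stack is *not* emitted, so the output
    has exactly ``(n−1)·m`` planes (21 sections at 7 μm → 140 planes at 1 μm).

    Parameters
    ----------
    vol : ScalarVolume
        Single-channel volume; needs at least two planes.
    target_z : float
        Output plane spacing in μm; must evenly divide ``vol.spacing[0]``.
    flow_radius : int
        Window radius of the iterative Lucas–Kanade flow estimator
        (window = 2·radius+1 px).
    flow_num_warp : int
        Warp/refine iterations of the flow estimator.
    """
    n = vol.shape[0]
    if n < 2:
        raise ValueError("interpolation needs at least two planes")
    z_spacing = vol.spacing[0]
    if target_z <= 0:
        raise ValueError("target_z must be positive")
    m = z_spacing / target_z
    if abs(m - round(m)) > 1e-9:
        raise ValueError(
            f"target_z={target_z} must evenly divide the z spacing {z_spacing}"
        )
    m = int(round(m))

    planes = vol.data.astype(np.float32)
    out = np.empty((m * (n - 1),) + vol.shape[1:], dtype=np.uint8)
    fracs = np.arange(1, m) / m
    for i in range(n - 1):
        a, b = planes[i], planes[i + 1]
        out[i * m] = vol.data[i]
        if m == 1:
            continue
        if np.array_equal(vol.data[i], vol.data[i + 1]):
            # identical planes: zero flow, every blend reproduces the input
            for j, _ in enumerate(fracs, start=1):
                out[i * m + j] = vol.data[i]
            continue
        # flow_ab registers b onto a: a(r) ≈ b(r + flow_ab(r))
        flow_ab = optical_flow_ilk(a, b, radius=flow_radius, num_warp=flow_num_warp)
        flow_ba = optical_flow_ilk(b, a, radius=flow_radius, num_warp=flow_num_warp)
        for j, t in enumerate(fracs, start=1):
            # flow_ab(p) points from a feature's position in a to its position
            # in b, so advecting a forward means sampling it at r - t*flow_ab;
            # symmetric bidirectional blending avoids ghosting at gap midpoints
            wa = _warp(a, flow_ab, -t)
            wb = _warp(b, flow_ba, -(1.0 - t))
            blend = (1.0 - t) * wa + t * wb
            out[i * m + j] = np.clip(np.rint(blend), 0, 255).astype(np.uint8)
    log.info("interpolated %d planes -> %d planes (z %.3g -> %.3g um)",
             n, len(out), z_spacing, target_z)
    return ScalarVolume(
        out, spacing=(target_z, vol.spacing[1], vol.spacing[2]), provenance="interpolated"
    )
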