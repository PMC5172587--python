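"""The six-filter segmentation chain applied to the interpolated saturation volume.

Order: Threshold 70 → Close 10 → Fill hole → Dilate 3 → Close 5 → Blur 0.33.
Thresholding coarsely segments stain from background; the large closing mends
gaps in vessel walls; hole filling makes lumina solid so large-vessel caliber
is measurable later; dilation and the second closing consolidate walls; the
final Gaussian blur smooths the surface the isosurface extractor will see.

Structuring elements are Euclidean balls measured in *voxels*, even though
voxels are anisotropic — smoothing is therefore physically stronger along z.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball

from .io import ScalarVolume, FilterChainConfig

log = logging.getLogger(__name__)

__all__ = [
    "threshold_volume",
    "grey_close",
    "fill_holes",
    "grey_dilate",
    "gaussian_blur",
    "apply_chain",
    "stage_difference_report",
]

_SIX_CONN = ndi.generate_binary_structure(3, 1)


def threshold_volume(vol: ScalarVolume, t: int = 70) -> ScalarVolume:
    """Set voxels with intensity strictly below ``t`` to 0; others pass unchanged."""
    if not 0 <= t <= 255:
        raise ValueError("threshold must be in [0, 255]")
    data = np.where(vol.data < t, 0, vol.data).astype(np.uint8)
    return ScalarVolume(data, vol.spacing, provenance=f"threshold_{t}")


def _ball_footprint(r: int) -> np.ndarray:
    if r < 1:
        raise ValueError("radius must be >= 1")
    return ball(r).astype(bool)


def grey_close(vol: ScalarVolume, r: int) -> ScalarVolume:
    """Grayscale closing (dilation then erosion) with a spherical element of radius ``r`` voxels."""
    fp = _ball_footprint(r)
    data = ndi.grey_erosion(ndi.grey_dilation(vol.data, footprint=fp), footprint=fp)
    return ScalarVolume(data, vol.spacing, provenance=f"close_{r}")


def grey_dilate(vol: ScalarVolume, r: int = 3) -> ScalarVolume:
    """Grayscale dilation with a spherical element of radius ``r`` voxels."""
    data = ndi.grey_dilation(vol.data, footprint=_ball_footprint(r))
    return ScalarVolume(data, vol.spacing, provenance=f"dilate_{r}")


def fill_holes(vol: ScalarVolume, per_slice: bool = False) -> ScalarVolume:
    """Fill enclosed background cavities (vessel lumina) with their shell's minimum intensity.

    Background voxels (value 0) that are not 6-connected to the volume border
    are interior cavities; each cavity is set to the minimum intensity found on
    its immediately surrounding shell of non-zero voxels.  With
    ``per_slice=True`` the same operation runs independently on every z plane
    (4-connected background).
    """
    data = vol.data.copy()
    if per_slice:
        for k in range(data.shape[0]):
            data[k] = _fill_plane_or_volume(data[k])
    else:
        data = _fill_plane_or_volume(data)
    return ScalarVolume(data, vol.spacing, provenance="fill_holes")


def _fill_plane_or_volume(data: np.ndarray) -> np.ndarray:
    bg = data == 0
    structure = ndi.generate_binary_structure(data.ndim, 1)
    labels, n = ndi.label(bg, structure=structure)
    if n == 0:
        return data
    # labels reaching any border stay background
    border = np.zeros(data.shape, bool)
    for ax in range(data.ndim):
        sl = [slice(None)] * data.ndim
        for idx in (0, -1):
            sl[ax] = idx
            border[tuple(sl)] = True
    open_ids = np.unique(labels[border & bg])
    enclosed = np.setdiff1d(np.arange(1, n + 1), open_ids)
    out = data.copy()
    for cid in enclosed:
        cavity = labels == cid
        shell = ndi.binary_dilation(cavity, structure=structure) & ~cavity
        shell_vals = data[shell]
        shell_vals = shell_vals[shell_vals > 0]
        fill = int(shell_vals.min()) if len(shell_vals) else 0
        out[cavity] = fill
    return out


def gaussian_blur(vol: ScalarVolume, sigma: float = 0.33) -> ScalarVolume:
    """3-D Gaussian blur, sigma in voxel units, reflecting boundary."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    blurred = ndi.gaussian_filter(vol.data.astype(np.float64), sigma=sigma, mode="reflect")
    data = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    return ScalarVolume(data, vol.spacing, provenance=f"blur_{sigma}")


def apply_chain(vol: ScalarVolume, chain: FilterChainConfig | None = None) -> ScalarVolume:
    """Run the six filters in their fixed order, logging per-stage support size."""
    chain = chain or FilterChainConfig()
    stages = [
        (f"threshold_{chain.threshold}", lambda v: threshold_volume(v, chain.threshold)),
        (f"close_{chain.close1_r}", lambda v: grey_close(v, chain.close1_r)),
    ]
    if chain.fill_holes:
        stages.append(("fill_holes", lambda v: fill_holes(v, chain.fill_holes_per_slice)))
    stages += [
        (f"dilate_{chain.dilate_r}", lambda v: grey_dilate(v, chain.dilate_r)),
        (f"close_{chain.close2_r}", lambda v: grey_close(v, chain.close2_r)),
        (f"blur_{chain.blur_sigma}", lambda v: gaussian_blur(v, chain.blur_sigma)),
    ]
    out = vol
    for name, fn in stages:
        out = fn(out)
        log.info("filter stage %-14s nonzero voxels: %d", name, int((out.data > 0).sum()))
    out.provenance = "filtered"
    return out


def _to_rgb(plane: np.ndarray) -> np.ndarray:
    if plane.ndim == 2:
        return np.stack([plane] * 3, axis=-1).astype(np.uint8)
    return plane.astype(np.uint8)


def stage_difference_report(
    interp: ScalarVolume,
    filtered: ScalarVolume,
    region: tuple[slice, slice] | None = None,
    *,
    stack=None,
    saturation: ScalarVolume | None = None,
    tolerance: int = 0,
    slice_indices: list[int] | None = None,
) -> list[np.ndarray]:
    """Six-panel QC montages showing what filtering changed, per inspected slice.

    Panels: original scan (if a stack is supplied), saturation of section i and
    of section i+1, the interpolated plane, the filtered plane, and the
    filtered plane with voxels where ``|filtered − interpolated| > tolerance``
    overlaid in red.

    Returns a list of RGB images (one montage per inspected plane).
    """
    if interp.shape != filtered.shape:
        raise ValueError(
            f"shape mismatch: interpolated {interp.shape} vs filtered {filtered.shape}"
        )
    region = region or (slice(None), slice(None))
    nz = interp.shape[0]
    if slice_indices is None:
        slice_indices = [nz // 2]
    # how many interpolated planes correspond to one original section
    planes_per_section = 1
    if saturation is not None and saturation.shape[0] > 1:
        planes_per_section = max(1, round(saturation.spacing[0] / interp.spacing[0]))

    montages = []
    for k in slice_indices:
        sec = k // planes_per_section
        panels = []
        if stack is not None:
            panels.append(_to_rgb(stack.slices[min(sec, stack.n_slices - 1)][region]))
        else:
            panels.append(_to_rgb(interp.data[k][region]))
        if saturation is not None:
            s0 = saturation.data[min(sec, saturation.shape[0] - 1)][region]
            s1 = saturation.data[min(sec + 1, saturation.shape[0] - 1)][region]
        else:
            s0 = s1 = interp.data[k][region]
        panels += [_to_rgb(s0), _to_rgb(s1), _to_rgb(interp.data[k][region])]
        filt = filtered.data[k][region]
        panels.append(_to_rgb(filt))
        diff = np.abs(filtered.data[k][region].astype(int) - interp.data[k][region].astype(int))
        overlay = _to_rgb(filt).copy()
        mask = diff > tolerance
        overlay[mask] = (255, 0, 0)
        panels.append(overlay)
        h = max(p.shape[0] for p in panels)
        w = max(p.shape[1] for p in panels)
        grid = np.zeros((2 * h + 3, 3 * w + 6, 3), np.uint8)
        for idx, p in enumerate(panels):
            r, c = divmod(idx, 3)
            grid[r * (h + 3) : r * (h + 3) + p.shape[0],
                 c * (w + 3) : c * (w + 3) + p.shape[1]] = p
        montages.append(grid)
    return montages
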