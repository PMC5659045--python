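"""Vessel segmentation from phase-congruency responses.

PC maps computed on the raw green channel and on the enhanced image are
multiplied pixel-wise (noise rarely survives in both), binarized by the
isodata iterative threshold and cleaned by area filtering. A skeleton of
the main arcade — the input to the parabola fit that localizes the optic
disc — is extracted from a bottom-hat response restricted to the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core_io import BinaryMask, ChannelImage, PipelineConfig
from .phasecong import PCParams, phase_congruency


@dataclass
class VesselResult:
    mask: BinaryMask
    skeleton: np.ndarray        # (n, 2) int array of (row, col)
    combined_pc: np.ndarray


def combine_pc(pc_raw: np.ndarray, pc_enh: np.ndarray) -> np.ndarray:
    """Pixel-level product of two PC maps, renormalized to [0, 1]."""
    if pc_raw.shape != pc_enh.shape:
        raise ValueError("PC maps must share a shape")
    prod = pc_raw * pc_enh
    peak = prod.max()
    if peak <= 0:
        warnings.warn("combined PC map is identically zero")
        return prod
    return prod / peak


def iterative_threshold(values: np.ndarray, tol: float = 1e-4) -> float:
    """Isodata fixed point: T = (mean(below T) + mean(at/above T)) / 2,
    iterated from the global mean."""
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("need at least two distinct finite values")
    t = float(v.mean())
    for _ in range(500):
        lo = v[v < t]
        hi = v[v >= t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def area_filter(mask: BinaryMask, min_area: int) -> BinaryMask:
    """Drop 8-connected components smaller than ``min_area`` pixels."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if min_area == 1:
        return BinaryMask(data=mask.data.copy(), label=mask.label)
    out = morphology.remove_small_objects(mask.data, max_size=min_area - 1,
                                          connectivity=2)
    return BinaryMask(data=out, label=mask.label)


def _prune_spurs(skel: np.ndarray, length: int) -> np.ndarray:
    """Iteratively remove endpoint pixels; short spurs vanish, the arcade
    backbone (whose ends also erode slightly) survives."""
    skel = skel.copy()
    kernel = np.ones((3, 3))
    for _ in range(length):
        neighbors = ndimage.convolve(skel.astype(int), kernel, mode="constant") - skel
        endpoints = skel & (neighbors <= 1)
        if not endpoints.any():
            break
        skel &= ~endpoints
    return skel


def _drop_blob_components(mask: np.ndarray,
                          max_compactness: float = 0.5) -> np.ndarray:
    """Remove compact (blob- or ring-shaped) components: vessels are
    elongated, so a component whose hole-filled shape has compactness
    4 pi A / P^2 above the cutoff is lesion-like, not vessel-like."""
    from skimage import measure

    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    out = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        filled = region.image_filled
        area = filled.sum()
        perim = max(measure.perimeter(filled), 1.0)
        compactness = 4 * np.pi * area / perim ** 2
        if compactness <= max_compactness:
            sl = region.slice
            out[sl] |= labels[sl] == region.label
    return out


def skeleton_main_arcade(mask: BinaryMask, green: ChannelImage,
                         cfg: PipelineConfig | None = None) -> np.ndarray:
    """1-px skeleton of the largest vessel component.

    The green channel's bottom-hat response (dark elongated structure)
    is thresholded and intersected with the vessel mask before thinning,
    which suppresses thin capillaries relative to the main veins.
    """
    cfg = cfg or PipelineConfig()
    if not mask.data.any():
        raise ValueError("no main vessels: empty mask")
    w = green.shape[1]
    radius = max(3, round(w * cfg.bottomhat_radius_frac))
    bh = morphology.black_tophat(green.data, morphology.disk(radius))
    try:
        t = iterative_threshold(bh[mask.data])
        strong = (bh >= t) & mask.data
    except ValueError:
        strong = mask.data
    if not strong.any():
        strong = mask.data
    skel = morphology.skeletonize(strong)
    skel = _prune_spurs(skel, cfg.spur_length)
    if not skel.any():
        skel = morphology.skeletonize(strong)   # pruning ate everything
    labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
    if n == 0:
        raise ValueError("no main vessels: empty skeleton")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    main = labels == (1 + int(np.argmax(sizes)))
    return np.column_stack(np.nonzero(main))


def segment_vessels(green: ChannelImage, enhanced: ChannelImage,
                    fov: np.ndarray | None = None,
                    cfg: PipelineConfig | None = None) -> VesselResult:
    """Full vessel stage: PC on both images, product, threshold, area filter,
    arcade skeleton."""
    cfg = cfg or PipelineConfig()
    params = PCParams.from_config(cfg)
    pc_raw = phase_congruency(green, params)
    pc_enh = phase_congruency(enhanced, params)
    combined = combine_pc(pc_raw, pc_enh)
    if fov is not None:
        # the aperture rim is a giant edge; keep a margin of about two of
        # the largest filter wavelengths out
        margin = int(round(2 * cfg.pc_wavelength_min * cfg.pc_scale_factor ** (cfg.pc_scales - 1)))
        inner = ndimage.binary_erosion(fov, iterations=margin)
        combined = combined * inner
    # threshold on the geometric-mean scale: the product of two PC maps is
    # bounded by their squares, so sqrt restores a PC-scale quantity and
    # keeps the isodata split from collapsing onto the strongest vessels
    ridge = np.sqrt(combined)
    try:
        t = iterative_threshold(ridge[ridge > 0])
    except ValueError:
        t = 0.5
    # PC peaks on both vessel walls; closing joins them into a band, and a
    # darkness gate against a local median background trims the bright halo
    band = morphology.closing(ridge >= t, morphology.disk(3))
    k = max(9, round(15 * green.shape[1] / 565))
    k += (k % 2 == 0)
    local_bg = ndimage.median_filter(green.data, size=k)
    dark = green.data < local_bg - 0.0125
    binary = BinaryMask(data=band & dark, label="vessels")
    binary = area_filter(binary, cfg.scaled_min_area(green.shape[1]))
    binary = BinaryMask(data=_drop_blob_components(binary.data), label="vessels")
    skel = skeleton_main_arcade(binary, green, cfg) if binary.data.any() else \
        np.zeros((0, 2), dtype=int)
    return VesselResult(mask=binary, skeleton=skel, combined_pc=combined)
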