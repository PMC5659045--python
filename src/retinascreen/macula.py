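"""Macula localization by dyadic wavelet candidates and gray-contour scoring.

The macula is the darkest near-circular region of the fundus, with an
inverse-Gaussian intensity profile. Candidate centers are the regional
minima of a coarse undecimated (a-trous) dyadic wavelet approximation
built with the quadratic-spline scaling filter {1/8, 3/8, 3/8, 1/8};
each candidate is then scored by how circular and concentric the
iso-intensity contours around it are, which separates the fovea from
hemorrhages and shading artifacts of similar darkness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .core_io import ChannelImage, PipelineConfig

QUADRATIC_SPLINE = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0


@dataclass
class MaculaResult:
    center: tuple[float, float]
    contour_score: float
    candidates: list            # (row, col, coarse value), darkest first


def qsdwt_smooth(data: np.ndarray, levels: int) -> np.ndarray:
    """Coarse approximation after `levels` a-trous quadratic-spline passes.

    At level j the filter taps are spaced 2**(j-1) pixels apart, so the
    support doubles each level without decimation.
    """
    out = data.astype(np.float64)
    for j in range(1, levels + 1):
        hole = 2 ** (j - 1)
        taps = np.zeros((len(QUADRATIC_SPLINE) - 1) * hole + 1)
        taps[::hole] = QUADRATIC_SPLINE
        out = ndimage.correlate1d(out, taps, axis=0, mode="reflect")
        out = ndimage.correlate1d(out, taps, axis=1, mode="reflect")
    return out


def qsdwt_candidates(green: ChannelImage, levels: int = 4,
                     fov: np.ndarray | None = None,
                     od_center: tuple[float, float] | None = None,
                     od_radius: float | None = None,
                     cfg: PipelineConfig | None = None) -> list:
    """Regional minima of the coarsest approximation, darkest first.

    Minima within ``macula_od_exclusion`` x OD radius of the OD center are
    discarded; at most ``macula_candidates`` survive.
    """
    cfg = cfg or PipelineConfig()
    if not 2 <= levels <= 5:
        raise ValueError("levels must be in [2, 5]")
    coarse = qsdwt_smooth(green.data, levels)
    search = np.ones_like(coarse, dtype=bool) if fov is None else \
        ndimage.binary_erosion(fov, iterations=max(2, green.shape[1] // 40))
    work = np.where(search, coarse, coarse.max() + 1.0)
    minima = morphology.local_minima(work, connectivity=2)
    minima &= search
    if not minima.any():
        raise ValueError("no candidates: no regional minima inside FOV")
    labels, n = ndimage.label(minima, structure=np.ones((3, 3)))
    cands = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(labels == i)
        r, c = float(rows.mean()), float(cols.mean())
        if od_center is not None and od_radius is not None:
            d = np.hypot(r - od_center[0], c - od_center[1])
            if d < cfg.macula_od_exclusion * od_radius:
                continue
        cands.append((r, c, float(coarse[int(r), int(c)])))
    if not cands:
        raise ValueError("no candidates outside the OD exclusion zone")
    cands.sort(key=lambda t: t[2])
    return cands[:cfg.macula_candidates]


def contour_score(green: ChannelImage, center: tuple[float, float],
                  r_m: float | None = None,
                  n_levels: int = 5) -> float:
    """Mean over iso-levels of (1/circularity) x concentricity.

    Circularity is perimeter^2 / (4 pi area) of the iso-region containing
    the center (1 for a circle, larger otherwise); concentricity is
    1 - (centroid offset / r_m). A radially symmetric dark blob scores
    near 1, ragged or eccentric blobs lower.
    """
    h, w = green.shape
    if r_m is None:
        r_m = w / 20.0
    r0, c0 = center
    half = int(round(r_m))
    rlo, rhi = int(round(r0)) - half, int(round(r0)) + half + 1
    clo, chi = int(round(c0)) - half, int(round(c0)) + half + 1
    if rlo < 0 or clo < 0 or rhi > h or chi > w:
        raise ValueError("contour window not fully inside image")
    # sensor noise makes iso-lines of the shallow macular dip ragged;
    # contour on a lightly smoothed window
    win = ndimage.gaussian_filter(green.data[rlo:rhi, clo:chi], 1.5)
    vmin, vmed = win.min(), np.median(win)
    if vmed - vmin < 1e-9:
        return 0.0
    cr, cc = r0 - rlo, c0 - clo
    scores = []
    for frac in np.linspace(0.15, 0.85, n_levels):
        level = vmin + frac * (vmed - vmin)
        region = win <= level
        labels, _ = ndimage.label(region, structure=np.ones((3, 3)))
        lab = labels[int(round(cr)), int(round(cc))]
        if lab == 0:
            scores.append(0.0)
            continue
        blob = labels == lab
        area = blob.sum()
        if area < 4:
            scores.append(0.0)
            continue
        props = measure.regionprops(blob.astype(int))[0]
        perim = max(props.perimeter, 1.0)
        circ = perim ** 2 / (4 * np.pi * area)
        circ = max(circ, 1.0)
        cy, cx = props.centroid
        offset = np.hypot(cy - cr, cx - cc)
        conc = max(0.0, 1.0 - offset / r_m)
        scores.append(conc / circ)
    return float(np.mean(scores))


def locate_macula(green: ChannelImage, candidates: list,
                  cfg: PipelineConfig | None = None) -> MaculaResult:
    """Pick the candidate with the most circular, concentric contours.

    The contour score is weighted by each candidate's depth in the coarse
    wavelet approximation: the macula is the darkest structure at that
    scale (small deep lesions are attenuated by the smoothing), so the
    weight encodes "darkest region with a near-circular shape".
    """
    cfg = cfg or PipelineConfig()
    if not candidates:
        raise ValueError("no macula candidates")
    r_m = green.shape[1] * cfg.macula_rm_frac
    vals = np.array([v for (_r, _c, v) in candidates])
    vmin, vmax = vals.min(), vals.max()
    span = vmax - vmin
    best, best_score = None, -1.0
    for (r, c, v) in candidates:
        try:
            s = contour_score(green, (r, c), r_m, cfg.macula_contour_levels)
        except ValueError:
            continue
        depth_w = 1.0 if span < 1e-12 else (vmax - v) / span
        s = s * (0.25 + 0.75 * depth_w)
        if s > best_score:
            best_score, best = s, (r, c)
    if best is None:
        # all windows clipped: fall back to the darkest candidate
        r, c, _ = candidates[0]
        best, best_score = (r, c), 0.0
    return MaculaResult(center=best, contour_score=best_score,
                        candidates=candidates)


def detect_macula(green: ChannelImage, fov: np.ndarray | None = None,
                  od_center: tuple[float, float] | None = None,
                  od_radius: float | None = None,
                  cfg: PipelineConfig | None = None) -> MaculaResult:
    cfg = cfg or PipelineConfig()
    cands = qsdwt_candidates(green, cfg.macula_levels, fov,
                             od_center, od_radius, cfg)
    return locate_macula(green, cands, cfg)
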