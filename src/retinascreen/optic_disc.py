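"""Optic-disc localization and segmentation.

The main vascular arcade is approximately a parabola whose vertex sits on
the optic disc. A least-squares quadratic is fitted to the vessel
skeleton in both orientations (col as a function of row, and row as a
function of col); the better fit's vertex seeds a sliding-window search
whose response at a point is

    R(u, v) = mean(A channel of LAB) x variance(I channel of HSI)

inside a disc-shaped window — the OD is simultaneously bright (high A
after channel selection) and crossed by dark vessels (high intensity
variance). The boundary is then segmented by a circular Hough transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, draw, morphology, transform

from .core_io import BinaryMask, FundusImage, PipelineConfig


class DegeneratePointSet(ValueError):
    """Points cannot support a quadratic fit (collinear or too few)."""


@dataclass
class Parabola:
    a0: float
    a1: float
    a2: float
    orientation: str            # "x_of_y": col = f(row); "y_of_x": row = f(col)
    vertex: tuple[float, float]  # (row, col)
    residual: float

    def __call__(self, k: np.ndarray) -> np.ndarray:
        return self.a0 * k ** 2 + self.a1 * k + self.a2


@dataclass
class ODResult:
    center: tuple[float, float]
    radius: float
    mask: BinaryMask
    window_response: float
    low_confidence: bool = False


def fit_parabola(points: np.ndarray, orientation: str = "y_of_x") -> Parabola:
    """Least-squares fit of l = a0 k^2 + a1 k + a2 by the normal equations.

    ``points`` is (n, 2) of (row, col). For ``y_of_x`` the independent
    coordinate k is the column; for ``x_of_y`` it is the row.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise DegeneratePointSet("need at least 3 points")
    if orientation == "y_of_x":
        k, l = pts[:, 1], pts[:, 0]
    elif orientation == "x_of_y":
        k, l = pts[:, 0], pts[:, 1]
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    # center k for conditioning, then map the coefficients back
    k0 = k.mean()
    kc = k - k0
    A = np.column_stack([kc ** 2, kc, np.ones_like(kc)])
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < 3 or np.linalg.cond(gram) > 1e12:
        raise DegeneratePointSet("degenerate point set")
    coef = np.linalg.solve(gram, A.T @ l)
    b0, b1, b2 = (float(c) for c in coef)
    # collinear data: the quadratic term contributes nothing over the span
    quad_contrib = abs(b0) * (np.ptp(kc) / 2.0) ** 2
    if quad_contrib < 1e-6 * (np.ptp(l) + 1.0):
        raise DegeneratePointSet("collinear points: a0 ~ 0, vertex undefined")
    a0 = b0
    a1 = b1 - 2.0 * b0 * k0
    a2 = b2 - b1 * k0 + b0 * k0 * k0
    resid = float(np.mean((A @ coef - l) ** 2))
    if a0 == 0:
        raise DegeneratePointSet("collinear points: a0 = 0, vertex undefined")
    k_star = -a1 / (2 * a0)
    l_star = a0 * k_star ** 2 + a1 * k_star + a2
    vertex = (l_star, k_star) if orientation == "y_of_x" else (k_star, l_star)
    return Parabola(a0, a1, a2, orientation, vertex, resid)


def candidate_arcade_fits(skeleton: np.ndarray,
                          img_shape: tuple[int, int] | None = None) -> list[Parabola]:
    """Both orientation fits (where non-degenerate), vertices clamped to the
    image bounds. When the skeleton covers only part of the arcade both
    orientations can fit it well, so downstream code should disambiguate by
    image evidence rather than residual alone."""
    if len(skeleton) == 0:
        raise DegeneratePointSet("empty skeleton")
    fits = []
    for orient in ("y_of_x", "x_of_y"):
        try:
            fits.append(fit_parabola(skeleton, orient))
        except DegeneratePointSet:
            pass
    if not fits:
        raise DegeneratePointSet("both parabola fits degenerate")
    if img_shape is not None:
        for p in fits:
            r = min(max(p.vertex[0], 0.0), img_shape[0] - 1.0)
            c = min(max(p.vertex[1], 0.0), img_shape[1] - 1.0)
            p.vertex = (r, c)
    return fits


def choose_arcade_fit(skeleton: np.ndarray,
                      img_shape: tuple[int, int] | None = None) -> Parabola:
    """The orientation with the smaller mean squared residual."""
    return min(candidate_arcade_fits(skeleton, img_shape),
               key=lambda p: p.residual)


def _lab_a(img: FundusImage) -> np.ndarray:
    return color.rgb2lab(img.rgb).astype(np.float64)[:, :, 1]


def _hsi_i(img: FundusImage) -> np.ndarray:
    return img.rgb.astype(np.float64).mean(axis=2) / 255.0


def window_response(img: FundusImage, center: tuple[float, float],
                    diameter: float,
                    a_chan: np.ndarray | None = None,
                    i_chan: np.ndarray | None = None) -> float:
    """R = mean(LAB A) x population variance(HSI I) inside the disc window."""
    h, w = img.shape
    r0, c0 = center
    rad = diameter / 2.0
    if r0 - rad < -0.5 or c0 - rad < -0.5 or r0 + rad > h - 0.5 or c0 + rad > w - 0.5:
        raise ValueError("window not fully inside image")
    rr, cc = draw.disk((r0, c0), rad, shape=(h, w))
    if rr.size == 0:
        raise ValueError("empty window")
    a_chan = _lab_a(img) if a_chan is None else a_chan
    i_chan = _hsi_i(img) if i_chan is None else i_chan
    return float(a_chan[rr, cc].mean() * i_chan[rr, cc].var())


def locate_od(img: FundusImage, parabola: Parabola,
              cfg: PipelineConfig | None = None) -> tuple[float, float]:
    """Grid-scan the ROI around the parabola vertex for the maximal window
    response."""
    cfg = cfg or PipelineConfig()
    h, w = img.shape
    diameter = w * cfg.od_window_frac
    rad = diameter / 2.0
    half = w * cfg.od_roi_frac / 2.0
    stride = max(1.0, diameter / 4.0)

    a_chan = _lab_a(img)
    i_chan = _hsi_i(img)
    # a window overlapping the black aperture rim has a spurious huge
    # variance, so the whole disc must sit inside the FOV
    selem = morphology.disk(int(np.ceil(rad)))
    valid = ndimage.binary_erosion(img.field_of_view_mask, structure=selem)

    def scan(r_lo, r_hi, c_lo, c_hi):
        best, best_pt = -np.inf, None
        rows = np.arange(max(r_lo, rad + 1), min(r_hi, h - rad - 1) + 1e-9, stride)
        cols = np.arange(max(c_lo, rad + 1), min(c_hi, w - rad - 1) + 1e-9, stride)
        for r in rows:
            for c in cols:
                if not valid[int(r), int(c)]:
                    continue
                resp = window_response(img, (r, c), diameter, a_chan, i_chan)
                if resp > best:
                    best, best_pt = resp, (float(r), float(c))
        return best_pt, best

    vertices = [parabola.vertex] if isinstance(parabola, Parabola) else \
        [p.vertex for p in parabola]
    best_pt, best_resp = None, -np.inf
    for (vr, vc) in vertices:
        pt, resp = scan(vr - half, vr + half, vc - half, vc + half)
        if pt is not None and resp > best_resp:
            best_pt, best_resp = pt, resp
    if best_pt is None:
        import warnings
        warnings.warn("empty OD ROI; falling back to full-image scan")
        best_pt, best_resp = scan(0, h, 0, w)
        if best_pt is None:
            raise ValueError("no valid OD window anywhere in the image")
    return best_pt


def segment_od(img: FundusImage, center: tuple[float, float],
               cfg: PipelineConfig | None = None) -> ODResult:
    """Circular Hough transform on the red-free luminance edges near the
    located center."""
    cfg = cfg or PipelineConfig()
    h, w = img.shape
    diameter = w * cfg.od_window_frac
    r_min = max(5, int(w * cfg.od_radius_frac_min))
    r_max = max(r_min + 2, int(w * cfg.od_radius_frac_max))
    half = int(0.75 * diameter) + r_max  # 1.5 x diameter window
    r0, c0 = int(round(center[0])), int(round(center[1]))
    rlo, rhi = max(0, r0 - half), min(h, r0 + half)
    clo, chi = max(0, c0 - half), min(w, c0 + half)
    lum = img.rgb[:, :, 1].astype(np.float64) / 255.0   # red-free
    patch = lum[rlo:rhi, clo:chi]

    gy, gx = np.gradient(patch)
    gmag = np.hypot(gy, gx)
    pos = gmag[gmag > 1e-12]
    if pos.size == 0:
        edges = np.zeros_like(gmag, dtype=bool)
    else:
        edges = gmag >= np.percentile(pos, 90)

    radii = np.arange(r_min, r_max + 1, 2)
    hough = transform.hough_circle(edges, radii)
    accums, cxs, cys, rads = transform.hough_circle_peaks(hough, radii,
                                                          total_num_peaks=1)
    default_radius = (r_min + r_max) / 2.0
    low_conf = True
    best_center = (float(center[0]), float(center[1]))
    best_radius = default_radius
    if len(accums) > 0:
        # normalized accumulator ~ fraction of the perimeter voting; a soft
        # or partially occluded rim splits votes across radius bins, so 0.4
        # accepts real discs while random edge maps stay near 0.25
        peak_quality = accums[0]
        if peak_quality >= 0.4:
            best_center = (float(cys[0] + rlo), float(cxs[0] + clo))
            best_radius = float(rads[0])
            low_conf = False

    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw.disk(best_center, best_radius, shape=(h, w))
    mask[rr, cc] = True
    resp = None
    try:
        resp = window_response(img, best_center, diameter)
    except ValueError:
        resp = float("nan")
    return ODResult(center=best_center, radius=best_radius,
                    mask=BinaryMask(data=mask, label="od"),
                    window_response=resp, low_confidence=low_conf)


def detect_od(img: FundusImage, skeleton: np.ndarray,
              cfg: PipelineConfig | None = None) -> ODResult:
    """Arcade fits -> window-response scan over each candidate vertex's ROI
    -> Hough segmentation around the winning point."""
    cfg = cfg or PipelineConfig()
    fits = candidate_arcade_fits(skeleton, img.shape)
    center = locate_od(img, fits, cfg)
    return segment_od(img, center, cfg)
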