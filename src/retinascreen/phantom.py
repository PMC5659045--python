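"""Synthetic fundus phantom with exact ground truth.

The generator emulates the image properties the detection stages rely
on: a circular field of view, a dark parabolic vascular arcade whose
vertex carries a bright optic disc, a dark near-Gaussian macula about
two disc-diameters temporal to the OD, small dark microaneurysm dots,
larger dark hemorrhage blobs, bright sharp-edged exudate patches,
radial vignetting and additive Gaussian noise. The green channel
carries the structural contrast; red and blue are plausible fills.

It is first-class, tested code: every mask and centroid in the returned
GroundTruth is exact by construction, which is what makes the pipeline
regression tests meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, FundusImage
from .grading import GradingResult, grade, quadrant_counts


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (584, 565)      # (H, W), DRIVE-like
    seed: int = 0
    # vessels
    arcade_open_right: bool | None = None     # None -> random per seed
    vessel_width_range: tuple[float, float] = (2.0, 7.0)   # px at 565 width
    vessel_depth_range: tuple[float, float] = (0.15, 0.30)  # fraction of bg
    n_branches: int = 3
    # optic disc
    od_radius_frac: float = 1.0 / 12.5        # x image width
    od_brightness: float = 0.30
    od_vertex_jitter: float = 10.0            # px, keeps OD on the vertex
    # macula
    macula_depth: float = 0.16
    macula_sigma_frac: float = 1.0 / 24.0     # x image width
    # lesions
    n_ma: int = 10
    ma_radius_range: tuple[float, float] = (1.0, 3.0)
    n_hemorrhage: int = 6
    hem_radius_range: tuple[float, float] = (4.0, 15.0)
    n_exudate: int = 6
    exu_radius_range: tuple[float, float] = (4.0, 10.0)
    dark_contrast_range: tuple[float, float] = (0.15, 0.40)   # red lesions
    bright_contrast_range: tuple[float, float] = (0.20, 0.50)  # exudates
    # photometry
    background_green: float = 0.42
    noise_sigma: float = 0.012
    vignette_strength: float = 0.12


@dataclass
class GroundTruth:
    masks: dict                      # label -> BinaryMask
    od_center: tuple[float, float]
    od_radius: float
    macula_center: tuple[float, float]
    ma_centroids: list
    hemorrhage_centroids: list
    exudate_centroids: list
    grade: GradingResult
    arcade: tuple = ()               # (a, vertex_r, vertex_c, open_right)


class PlacementError(RuntimeError):
    """Could not place a structure after the rejection budget."""


def _fov_mask(shape: tuple[int, int]) -> tuple[np.ndarray, tuple[float, float], float]:
    h, w = shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.48 * min(h, w)
    rr, cc_ = np.mgrid[0:h, 0:w]
    mask = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius ** 2
    return mask, (cr, cc), radius


def _gaussian_dot(shape, center, sigma_r, sigma_c=None, theta=0.0):
    h, w = shape
    sigma_c = sigma_c or sigma_r
    r0, c0 = center
    half = int(4 * max(sigma_r, sigma_c)) + 2
    rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    g = np.exp(-(u ** 2 / (2 * sigma_r ** 2) + v ** 2 / (2 * sigma_c ** 2)))
    out = np.zeros(shape)
    out[rlo:rhi, clo:chi] = g
    return out


def _render_curve_distance(shape, points: np.ndarray) -> np.ndarray:
    """Distance from every pixel to the (densely sampled) curve."""
    canvas = np.ones(shape, dtype=bool)
    pts = np.round(points).astype(int)
    h, w = shape
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[ok]
    canvas[pts[:, 0], pts[:, 1]] = False
    return ndimage.distance_transform_edt(canvas)


def generate(spec: PhantomSpec | None = None) -> tuple[FundusImage, GroundTruth]:
    """Render a phantom and its exact ground truth, deterministically in
    ``spec.seed``."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    fov, (fcr, fcc), frad = _fov_mask(spec.shape)
    scale = w / 565.0

    green = np.full(spec.shape, spec.background_green)
    # gentle illumination gradient
    rr, cc = np.mgrid[0:h, 0:w]
    green += 0.02 * ((cc - fcc) / frad) * rng.uniform(-1, 1)

    # ---- vascular arcade --------------------------------------------------
    open_right = spec.arcade_open_right
    if open_right is None:
        open_right = bool(rng.integers(2))
    sign = 1.0 if open_right else -1.0
    vertex_r = fcr + rng.uniform(-0.08, 0.08) * frad
    vertex_c = fcc - sign * rng.uniform(0.50, 0.58) * frad
    span = 0.72 * frad
    reach = rng.uniform(1.05, 1.2) * frad
    a = sign * reach / span ** 2

    vessel_field = np.zeros(spec.shape)
    vessel_mask = np.zeros(spec.shape, dtype=bool)
    t = np.linspace(-span, span, int(4 * span))
    curves = [(a, 1.0)]
    for _ in range(spec.n_branches - 1):
        curves.append((a * rng.uniform(1.4, 2.6), rng.uniform(0.5, 0.8)))
    wmin, wmax = spec.vessel_width_range
    for branch_idx, (a_i, rel_width) in enumerate(curves):
        pts = np.column_stack([vertex_r + t, vertex_c + a_i * t ** 2])
        dist = _render_curve_distance(spec.shape, pts)
        # the main arcade is the widest vessel; branches are thinner
        lo = wmin + 0.7 * (wmax - wmin) if branch_idx == 0 else wmin
        width = max(wmin, rng.uniform(lo, wmax) * rel_width) * scale
        # wider vessels are darker, as the main veins are in real fundus images
        dmin, dmax = spec.vessel_depth_range
        depth = (dmin + (dmax - dmin) * (width / scale - wmin) / (wmax - wmin)
                 ) * rng.uniform(0.9, 1.1) * spec.background_green
        # flat-top profile with crisp walls, as in a focused fundus photo
        profile = 1.0 / (1.0 + np.exp(np.clip((dist - width / 2.0) / 0.8, -60, 60)))
        vessel_field = np.maximum(vessel_field, depth * profile)
        vessel_mask |= dist <= max(1.0, width / 2.0)
    vessel_mask &= fov
    green -= vessel_field

    # ---- optic disc at the arcade vertex ---------------------------------
    od_radius = spec.od_radius_frac * w
    od_center = (vertex_r + rng.uniform(-1, 1) * spec.od_vertex_jitter,
                 vertex_c + rng.uniform(-1, 1) * spec.od_vertex_jitter)
    d_od = np.hypot(rr - od_center[0], cc - od_center[1])
    od_profile = 1.0 / (1.0 + np.exp((d_od - od_radius) / (0.08 * od_radius)))
    green += spec.od_brightness * od_profile
    od_mask = d_od <= od_radius

    # ---- macula ----------------------------------------------------------
    mac_sigma = spec.macula_sigma_frac * w
    mac_center = (vertex_r + rng.uniform(-0.04, 0.04) * frad,
                  vertex_c + sign * (rng.uniform(4.4, 5.0) * od_radius))
    green -= spec.macula_depth * _gaussian_dot(spec.shape, mac_center, mac_sigma)
    mac_mask = np.hypot(rr - mac_center[0], cc - mac_center[1]) <= 2 * mac_sigma

    # ---- lesions ----------------------------------------------------------
    margin = 20 * scale
    occupied = ndimage.binary_dilation(vessel_mask, iterations=int(3 * scale) + 1) \
        | ndimage.binary_dilation(od_mask, iterations=int(6 * scale))
    inside = ndimage.binary_erosion(fov, iterations=int(margin)) \
        & (np.hypot(rr - mac_center[0], cc - mac_center[1]) > 1.2 * mac_sigma)

    def place(radius: float, keepout: np.ndarray, attempts: int = 1000):
        for _ in range(attempts):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            ri, ci = int(r0), int(c0)
            if not inside[ri, ci] or keepout[ri, ci]:
                continue
            d = np.hypot(rr - r0, cc - c0)
            if (keepout & (d <= radius + 4)).any():
                continue
            return (r0, c0)
        raise PlacementError("no room for lesion after rejection attempts")

    masks = {lbl: np.zeros(spec.shape, dtype=bool)
             for lbl in ("ma", "hemorrhage", "exudate")}
    centroids = {"ma": [], "hemorrhage": [], "exudate": []}
    keepout = occupied.copy()

    def stamp_keepout(center, radius):
        d = np.hypot(rr - center[0], cc - center[1])
        np.logical_or(keepout, d <= radius + 6 * scale, out=keepout)

    for _ in range(spec.n_ma):
        rad = rng.uniform(*spec.ma_radius_range) * scale
        ctr = place(rad, keepout)
        contrast = rng.uniform(*spec.dark_contrast_range) * spec.background_green
        green -= contrast * _gaussian_dot(spec.shape, ctr, max(0.8, rad / 1.2))
        d = np.hypot(rr - ctr[0], cc - ctr[1])
        masks["ma"] |= d <= rad
        centroids["ma"].append(ctr)
        stamp_keepout(ctr, rad)

    for _ in range(spec.n_hemorrhage):
        rad = rng.uniform(*spec.hem_radius_range) * scale
        ctr = place(rad, keepout)
        contrast = rng.uniform(*spec.dark_contrast_range) * spec.background_green
        ratio = rng.uniform(1.0, 1.6)
        theta = rng.uniform(0, np.pi)
        dr, dc = rr - ctr[0], cc - ctr[1]
        u = dr * math.cos(theta) + dc * math.sin(theta)
        v = -dr * math.sin(theta) + dc * math.cos(theta)
        de = np.hypot(u, v * ratio)
        # irregular blot boundary: smooth angular wobble, as real dot/blot
        # hemorrhages are ragged rather than elliptical
        ang = np.arctan2(v, u)
        wobble = np.ones_like(de)
        for _h in range(2):
            kh = rng.integers(2, 6)
            wobble += rng.uniform(0.05, 0.15) * np.cos(kh * ang + rng.uniform(0, 2 * np.pi))
        d_eff = de / np.maximum(wobble, 0.5)
        blob = 1.0 / (1.0 + np.exp(np.clip((d_eff - rad) / 1.2, -60, 60)))
        green -= contrast * blob
        masks["hemorrhage"] |= d_eff <= rad
        centroids["hemorrhage"].append(ctr)
        stamp_keepout(ctr, rad)

    for _ in range(spec.n_exudate):
        rad = rng.uniform(*spec.exu_radius_range) * scale
        ctr = place(rad, keepout)
        contrast = rng.uniform(*spec.bright_contrast_range) * spec.background_green
        d = np.hypot(rr - ctr[0], cc - ctr[1])
        ratio = rng.uniform(1.0, 1.5)
        theta = rng.uniform(0, np.pi)
        dr, dc = rr - ctr[0], cc - ctr[1]
        u = dr * math.cos(theta) + dc * math.sin(theta)
        v = -dr * math.sin(theta) + dc * math.cos(theta)
        de = np.hypot(u, v * ratio)
        patch = 1.0 / (1.0 + np.exp(np.clip((de - rad) / 0.7, -60, 60)))  # sharp edge
        green += contrast * patch
        masks["exudate"] |= de <= rad
        centroids["exudate"].append(ctr)
        stamp_keepout(ctr, rad)

    # ---- photometry -------------------------------------------------------
    d_fov = np.hypot(rr - fcr, cc - fcc) / frad
    vignette = 1.0 - spec.vignette_strength * np.clip(d_fov, 0, 1) ** 2
    green *= vignette
    green += rng.normal(0.0, spec.noise_sigma, spec.shape)
    green = np.clip(green, 0.0, 1.0)
    green[~fov] = 0.0

    red = np.clip(green * 1.8 + 0.18, 0, 1)
    red[~fov] = 0.0
    blue = np.clip(green * 0.35, 0, 1)
    rgb = np.stack([red, green, blue], axis=2)
    rgb = np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)
    # keep the FOV detectable even where green is dark
    rgb[:, :, 0][fov] = np.maximum(rgb[:, :, 0][fov], 30)

    img = FundusImage(rgb=rgb, field_of_view_mask=fov,
                      source_id=f"phantom-{spec.seed}")

    gt_masks = {
        "vessels": BinaryMask(data=vessel_mask, label="vessels"),
        "od": BinaryMask(data=od_mask, label="od"),
        "macula": BinaryMask(data=mac_mask, label="macula"),
        "ma": BinaryMask(data=masks["ma"], label="ma"),
        "hemorrhage": BinaryMask(data=masks["hemorrhage"], label="hemorrhage"),
        "exudate": BinaryMask(data=masks["exudate"], label="exudate"),
    }
    q = quadrant_counts(centroids["hemorrhage"], mac_center)
    true_grade = grade(len(centroids["ma"]), len(centroids["hemorrhage"]),
                       len(centroids["exudate"]), q)
    gt = GroundTruth(masks=gt_masks, od_center=od_center, od_radius=od_radius,
                     macula_center=mac_center,
                     ma_centroids=centroids["ma"],
                     hemorrhage_centroids=centroids["hemorrhage"],
                     exudate_centroids=centroids["exudate"],
                     grade=true_grade,
                     arcade=(a, vertex_r, vertex_c, open_right))
    return img, gt


# ---------------------------------------------------------------------------
# training tables
# ---------------------------------------------------------------------------

def _overlap_fraction(region: np.ndarray, mask: np.ndarray) -> float:
    hits = mask[region[:, 0], region[:, 1]].sum()
    return hits / len(region)


def make_training_table(n_images: int = 12, seed: int = 0,
                        base_spec: PhantomSpec | None = None) -> list[dict]:
    """Labelled hemorrhage-stage feature rows harvested from phantoms.

    Candidate extraction runs with vessel removal disabled so vessel
    fragments appear as negatives; candidates overlapping a ground-truth
    mask by >= 50% take that class, others are labelled by provenance
    (vessel fragment vs background).
    """
    from .core_io import PipelineConfig, green_channel
    from .preprocess import enhance
    from .red_lesions import hemorrhage_candidates

    if n_images < 1:
        raise ValueError("need at least one phantom")
    rows = []
    for i in range(n_images):
        spec = base_spec or PhantomSpec()
        spec = PhantomSpec(**{**spec.__dict__, "seed": seed + 1000 + i})
        img, gt = generate(spec)
        cfg = PipelineConfig(seed=seed)
        green = green_channel(img)
        enhanced = enhance(green, cfg, fov=img.field_of_view_mask)
        cands = hemorrhage_candidates(
            enhanced, green, gt.masks["vessels"],
            od_mask=gt.masks["od"].data, fov=img.field_of_view_mask,
            cfg=cfg, remove_vessel_overlap=False)
        for c in cands:
            if _overlap_fraction(c.mask, gt.masks["hemorrhage"].data) >= 0.5:
                label = "hemorrhage"
            elif _overlap_fraction(c.mask, gt.masks["ma"].data) >= 0.5:
                continue       # MAs are not hemorrhage-stage samples
            elif _overlap_fraction(
                    c.mask, ndimage.binary_dilation(gt.masks["vessels"].data,
                                                    iterations=2)) >= 0.5:
                label = "vessel"
            else:
                label = "background"
            rows.append({**c.features, "label": label})
    for cls in ("hemorrhage", "vessel", "background"):
        if not any(r["label"] == cls for r in rows):
            raise ValueError(f"training table has no samples of class {cls!r}")
    return rows


def make_exudate_table(n_images: int = 12, seed: int = 0,
                       base_spec: PhantomSpec | None = None) -> list[dict]:
    """Labelled exudate-stage rows: candidates are extracted without OD
    removal so the disc itself provides hard negatives."""
    from .bright_lesions import background_morph, edge_strength_map, exudate_candidates
    from .core_io import PipelineConfig, green_channel

    rows = []
    for i in range(n_images):
        spec = base_spec or PhantomSpec()
        spec = PhantomSpec(**{**spec.__dict__, "seed": seed + 2000 + i})
        img, gt = generate(spec)
        cfg = PipelineConfig(seed=seed)
        green = green_channel(img)
        B = background_morph(green, cfg=cfg)
        edges = edge_strength_map(green)
        cands = exudate_candidates(B, edges, od=None,
                                   fov=img.field_of_view_mask, cfg=cfg,
                                   green=green, loose=True)
        for c in cands:
            if _overlap_fraction(c.mask, gt.masks["exudate"].data) >= 0.5:
                label = "exudate"
            elif _overlap_fraction(c.mask, gt.masks["od"].data) >= 0.5:
                label = "od"
            else:
                label = "background"
            rows.append({**c.features, "label": label})
    if not any(r["label"] == "exudate" for r in rows):
        raise ValueError("training table has no exudate samples")
    if not any(r["label"] != "exudate" for r in rows):
        raise ValueError("training table has no negative samples")
    return rows
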