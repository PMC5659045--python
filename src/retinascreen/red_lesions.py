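"""Microaneurysm and hemorrhage detection.

MAs: phase congruency of the inverted green channel at small scales
yields candidate dots; each candidate's W x W neighborhood is scanned
along 8 fixed directions and every cross-section profile is scored
against 7 peak-shape criteria (0-56 total), which separates round dots
from vessel fragments.

Hemorrhages: the CLAHE-enhanced image minus a large median-filter
background isolates dark structure; 1-D k-means (K=5) on the difference
intensities picks the darkest clusters as candidates; vessels are
removed, candidate shapes are refined by adaptive region growing, and a
two-stage SVM cascade (shape features, then gray features) rejects
vessel fragments and background residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.model_selection import cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core_io import BinaryMask, ChannelImage, PipelineConfig
from .phasecong import PCParams, phase_congruency
from .vessels import iterative_threshold

# the 8 published scan directions, degrees
PROFILE_DIRECTIONS = (0.0, 22.0, 45.0, 66.0, 90.0, 111.0, 135.0, 156.0)

SHAPE_FEATURES = ("eccentricity", "circularity", "axis_ratio")
GRAY_FEATURES = ("m_in", "m_out", "m_d")
FEATURE_NAMES = SHAPE_FEATURES + GRAY_FEATURES


@dataclass
class MAProfileSet:
    window: np.ndarray                  # W x W patch, inverted green
    profiles: np.ndarray                # 8 x W
    hits: np.ndarray = None             # per-direction criterion counts
    score: int = 0


@dataclass
class LesionCandidate:
    mask: np.ndarray                    # (n, 2) pixel coordinates
    centroid: tuple[float, float]
    features: dict = field(default_factory=dict)
    kind: str = "hemorrhage"            # ma | hemorrhage | exudate
    clipped: bool = False


@dataclass
class KMeansModel:
    K: int
    centers: np.ndarray
    objective: float
    objective_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# microaneurysms
# ---------------------------------------------------------------------------

def ma_candidates(green: ChannelImage, vessels: BinaryMask | None = None,
                  od_mask: np.ndarray | None = None,
                  fov: np.ndarray | None = None,
                  cfg: PipelineConfig | None = None) -> list[tuple[int, int]]:
    """Dot candidates: PC peaks of the inverted green channel at small
    wavelengths, off the (dilated) vessel tree and the optic disc."""
    cfg = cfg or PipelineConfig()
    inv = ChannelImage(data=1.0 - green.data, domain="enhanced")
    params = PCParams.from_config(cfg, wavelength_min=cfg.ma_pc_wavelength_min)
    pc = phase_congruency(inv, params)

    allowed = np.ones(pc.shape, dtype=bool)
    if fov is not None:
        allowed &= ndimage.binary_erosion(fov, iterations=cfg.ma_window)
    if vessels is not None and vessels.data.any():
        allowed &= ~ndimage.binary_dilation(vessels.data, iterations=2)
    if od_mask is not None:
        allowed &= ~od_mask
    vals = pc[allowed & (pc > 0)]
    if vals.size < 2 or np.ptp(vals) == 0:
        return []
    t = iterative_threshold(vals)
    peaks = morphology.local_maxima(pc, connectivity=2) & (pc >= t) & allowed
    labels, n = ndimage.label(peaks, structure=np.ones((3, 3)))
    cents = ndimage.center_of_mass(peaks, labels, np.arange(1, n + 1))
    return [(int(round(r)), int(round(c))) for r, c in cents]


def cross_section_profiles(green_inverted: ChannelImage | np.ndarray,
                           center: tuple[int, int], W: int = 15) -> MAProfileSet:
    """Sample 8 length-W nearest-neighbor profiles through ``center``."""
    data = green_inverted.data if isinstance(green_inverted, ChannelImage) \
        else np.asarray(green_inverted, dtype=np.float64)
    if W % 2 == 0:
        raise ValueError("W must be odd")
    h, w = data.shape
    r0, c0 = center
    half = W // 2
    if r0 - half < 0 or c0 - half < 0 or r0 + half >= h or c0 + half >= w:
        raise ValueError("window clipped by image border")
    window = data[r0 - half:r0 + half + 1, c0 - half:c0 + half + 1]
    steps = np.arange(-half, half + 1, dtype=np.float64)
    profiles = np.empty((len(PROFILE_DIRECTIONS), W))
    kernel = np.array([0.25, 0.5, 0.25])
    for i, deg in enumerate(PROFILE_DIRECTIONS):
        ang = np.deg2rad(deg)
        rr = np.clip(np.round(r0 - steps * np.sin(ang)).astype(int), 0, h - 1)
        cc = np.clip(np.round(c0 + steps * np.cos(ang)).astype(int), 0, w - 1)
        p = data[rr, cc]
        # light binomial smoothing so sensor noise does not mimic peaks
        profiles[i] = np.convolve(np.r_[p[1], p, p[-2]], kernel, mode="valid")
    return MAProfileSet(window=window, profiles=profiles)


def _profile_criteria(p: np.ndarray, h_min: float, s_max: float) -> int:
    """Evaluate the 7 peak-shape criteria on one profile (MA = bright peak
    in the inverted green channel).

    The first criterion — a central local maximum with prominence at least
    h_min over both shoulders — gates the rest: without a significant peak
    the remaining shape measurements are noise and the direction scores 0.
    """
    W = len(p)
    half = W // 2
    hits = 0
    # 1. a significant local-maximum peak exists
    interior = p[1:-1]
    peak_idx = None
    if interior.size:
        rel = 1 + int(np.argmax(interior))
        if p[rel] > p[rel - 1] and p[rel] >= p[rel + 1]:
            peak_idx = rel
    if peak_idx is None:
        return 0
    peak = p[peak_idx]
    left_base = p[:peak_idx].min()
    right_base = p[peak_idx + 1:].min() if peak_idx + 1 < W else peak
    prom = peak - max(left_base, right_base)
    if prom < h_min:
        return 0
    hits += 1
    # 2. strong peak: prominence at least twice the floor
    if prom >= 2 * h_min:
        hits += 1
    # 3. width at half prominence within [1, W/2]
    half_level = peak - 0.5 * max(prom, 1e-12)
    li = peak_idx
    while li > 0 and p[li - 1] >= half_level:
        li -= 1
    ri = peak_idx
    while ri < W - 1 and p[ri + 1] >= half_level:
        ri += 1
    width = ri - li + 1
    if 1 <= width <= W / 2:
        hits += 1
    # 4/5. flat baselines: prominence-normalized slope of the outer quarter
    # of each side below s_max per pixel (normalization makes the criterion
    # invariant to intensity gain)
    quarter = max(3, W // 4)

    def base_slope(seg: np.ndarray) -> float:
        if len(seg) < 2:
            return 0.0
        x = np.arange(len(seg))
        return abs(np.polyfit(x, seg, 1)[0]) / prom
    if base_slope(p[:quarter]) <= s_max:
        hits += 1
    if base_slope(p[W - quarter:]) <= s_max:
        hits += 1
    # 6. peak centered within +/- 2 px of the window center
    if abs(peak_idx - half) <= 2:
        hits += 1
    # 7. shoulder symmetry: ratio of the two peak-to-baseline drops in [0.5, 2]
    dl = peak - left_base
    dr = peak - right_base
    if dl > 1e-12 and dr > 1e-12 and 0.5 <= dl / dr <= 2.0:
        hits += 1
    return hits


def ma_score(ps: MAProfileSet, h_min: float = 0.05,
             s_max: float = 0.02) -> int:
    """Total criterion hits over the 8 directions (0..56)."""
    hits = np.array([_profile_criteria(p, h_min, s_max) for p in ps.profiles])
    ps.hits = hits
    ps.score = int(hits.sum())
    return ps.score


def ma_accept(score: int, cfg: PipelineConfig | None = None) -> bool:
    cfg = cfg or PipelineConfig()
    if cfg.ma_accept_mode == "range":
        lo, hi = cfg.ma_score_range
        return lo <= score <= hi
    return score >= cfg.ma_score_min


def detect_mas(green: ChannelImage, vessels: BinaryMask | None = None,
               od_mask: np.ndarray | None = None,
               fov: np.ndarray | None = None,
               cfg: PipelineConfig | None = None) -> list[LesionCandidate]:
    cfg = cfg or PipelineConfig()
    inv = 1.0 - green.data
    accepted = []
    for (r, c) in ma_candidates(green, vessels, od_mask, fov, cfg):
        try:
            ps = cross_section_profiles(inv, (r, c), cfg.ma_window)
        except ValueError:
            continue                      # clipped by the border: discard
        score = ma_score(ps, cfg.ma_h_min, cfg.ma_s_max)
        if ma_accept(score, cfg):
            accepted.append((r, c, score))
    # merge acceptances within 4 px of each other (one dot, several peaks)
    accepted.sort(key=lambda t: -t[2])
    out: list[LesionCandidate] = []
    for (r, c, score) in accepted:
        if any(np.hypot(r - m.centroid[0], c - m.centroid[1]) <= 4 for m in out):
            continue
        out.append(LesionCandidate(mask=np.array([[r, c]]),
                                   centroid=(float(r), float(c)),
                                   features={"score": score}, kind="ma"))
    return out


# ---------------------------------------------------------------------------
# hemorrhages
# ---------------------------------------------------------------------------

def hemorrhage_background(enhanced: ChannelImage,
                          cfg: PipelineConfig | None = None) -> ChannelImage:
    """Difference image: enhanced minus a large median-filter background."""
    cfg = cfg or PipelineConfig()
    k = cfg.scaled_median_kernel(enhanced.shape[1])
    bg = ndimage.median_filter(enhanced.data, size=k, mode="reflect")
    return ChannelImage(data=enhanced.data - bg, domain="difference")


def kmeans_segment(D: ChannelImage, K: int = 5, seed: int = 0,
                   tol: float = 1e-6, max_iter: int = 300
                   ) -> tuple[KMeansModel, np.ndarray]:
    """1-D Lloyd k-means on pixel intensities with quantile initialization.

    The clustering objective E = sum_i sum_{x in C_i} (x - c_i)^2 is
    recorded every iteration and asserted non-increasing.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    x = D.data.ravel()
    uniq = np.unique(x)
    if uniq.size < K:
        warnings.warn(f"only {uniq.size} distinct values; reducing K")
        K = max(2, uniq.size)
        if uniq.size < 2:
            raise ValueError("constant image cannot be clustered")
    centers = np.quantile(x, (np.arange(K) + 0.5) / K)
    centers = np.unique(centers)
    while centers.size < K:   # duplicate quantiles on discrete data
        centers = np.unique(np.concatenate([centers, centers + 1e-9 * (1 + np.arange(K - centers.size))]))
    centers = np.sort(centers[:K])
    history = []
    prev_e = np.inf
    for _ in range(max_iter):
        # assignment step: nearest center (1-D -> boundary bisection)
        bounds = (centers[1:] + centers[:-1]) / 2.0
        labels = np.searchsorted(bounds, x)
        e = 0.0
        new_centers = centers.copy()
        for i in range(K):
            sel = x[labels == i]
            if sel.size:
                new_centers[i] = sel.mean()
                e += float(((sel - centers[i]) ** 2).sum())
        history.append(e)
        if e > prev_e + 1e-8 * max(1.0, abs(prev_e)):
            raise AssertionError("k-means objective increased")
        if abs(prev_e - e) < tol or np.max(np.abs(new_centers - centers)) < tol:
            centers = new_centers
            break
        centers = np.sort(new_centers)
        prev_e = e
    bounds = (centers[1:] + centers[:-1]) / 2.0
    label_img = np.searchsorted(bounds, D.data)
    model = KMeansModel(K=K, centers=centers, objective=history[-1],
                        objective_history=history)
    return model, label_img


def darkest_cluster_mask(model: KMeansModel, label_img: np.ndarray,
                         D: ChannelImage) -> np.ndarray:
    """Clusters whose center sits below mean - 0.5 std of the difference
    image are candidate (dark) structure."""
    cutoff = D.data.mean() - 0.5 * D.data.std()
    dark = np.nonzero(model.centers < cutoff)[0]
    if dark.size == 0:
        dark = np.array([int(np.argmin(model.centers))])
    return np.isin(label_img, dark)


def remove_vessels(cands: BinaryMask, vessels: BinaryMask) -> BinaryMask:
    """Subtract the dilated vessel tree; components mostly explained by
    vessels (> 80% overlap) are dropped entirely."""
    if cands.shape != vessels.shape:
        raise ValueError("shape mismatch")
    dil = ndimage.binary_dilation(vessels.data, iterations=2)
    labels, n = ndimage.label(cands.data, structure=np.ones((3, 3)))
    out = np.zeros_like(cands.data)
    for i in range(1, n + 1):
        comp = labels == i
        overlap = (comp & dil).sum() / comp.sum()
        if overlap > 0.8:
            continue
        out |= comp & ~dil
    return BinaryMask(data=out, label="candidate")


def region_grow(green: ChannelImage, seed_point: tuple[int, int],
                t0: float = 100.0 / 255.0,
                bbox: tuple[int, int, int, int] | None = None,
                area_cap: int | None = None) -> np.ndarray:
    """Adaptive 8-connected flood from the seed.

    A pixel joins the region iff |f - m| < t0 (m = running region mean)
    and f < T, where T is Otsu's threshold over a local window (3x the
    candidate bounding box, or the whole image if none is given).
    Returns an (n, 2) array of pixel coordinates.
    """
    from skimage.filters import threshold_otsu

    data = green.data
    h, w = data.shape
    r0, c0 = seed_point
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("seed outside image")
    if bbox is None:
        rlo, rhi, clo, chi = 0, h, 0, w
    else:
        br0, bc0, br1, bc1 = bbox
        hh, ww = br1 - br0, bc1 - bc0
        rlo = max(0, br0 - hh)
        rhi = min(h, br1 + hh)
        clo = max(0, bc0 - ww)
        chi = min(w, bc1 + ww)
    window = data[rlo:rhi, clo:chi]
    try:
        T = float(threshold_otsu(window))
    except ValueError:
        T = float(window.mean())
    if area_cap is None:
        area_cap = max(100, (rhi - rlo) * (chi - clo))

    f_seed = data[r0, c0]
    if not (f_seed < T):
        return np.array([[r0, c0]])
    grown = {(r0, c0)}
    mean = f_seed
    total = f_seed
    frontier = [(r0, c0)]
    while frontier and len(grown) < area_cap:
        nr0, nc0 = frontier.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                r, c = nr0 + dr, nc0 + dc
                if not (rlo <= r < rhi and clo <= c < chi):
                    continue
                if (r, c) in grown:
                    continue
                f = data[r, c]
                if abs(f - mean) < t0 and f < T:
                    grown.add((r, c))
                    total += f
                    mean = total / len(grown)
                    frontier.append((r, c))
    return np.array(sorted(grown))


def extract_features(region: np.ndarray, green: ChannelImage) -> dict:
    """The six shape/gray features of a candidate region.

    circularity = p^2 / (4 pi a); axis ratio from the ellipse with equal
    second-order central moments; m_out over a 2-px ring around the
    region.
    """
    region = np.asarray(region)
    if len(region) < 4:
        raise ValueError("region too small for features")
    h, w = green.shape
    mask = np.zeros((h, w), dtype=bool)
    mask[region[:, 0], region[:, 1]] = True
    props = measure.regionprops(mask.astype(int))[0]
    area = props.area
    perim = max(props.perimeter, 1.0)
    l1 = props.axis_major_length
    l2 = max(props.axis_minor_length, 1e-9)
    ring = ndimage.binary_dilation(mask, iterations=2) & ~mask
    clipped = bool(mask[0, :].any() or mask[-1, :].any()
                   or mask[:, 0].any() or mask[:, -1].any())
    m_in = float(green.data[mask].mean())
    m_out = float(green.data[ring].mean()) if ring.any() else m_in
    return {
        "eccentricity": float(props.eccentricity),
        "circularity": float(perim ** 2 / (4 * np.pi * area)),
        "axis_ratio": float(l1 / l2),
        "m_in": m_in,
        "m_out": m_out,
        "m_d": m_out - m_in,
        "clipped": clipped,
    }


# ---------------------------------------------------------------------------
# cascade classifier
# ---------------------------------------------------------------------------

@dataclass
class CascadeModel:
    """Two-stage SVM: shape features reject vessel fragments, gray features
    reject background/laser residue."""
    shape_clf: object = None
    gray_clf: object = None
    cv_accuracy: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def trained(self) -> bool:
        return self.shape_clf is not None and self.gray_clf is not None


def _feature_matrix(rows: list[dict], names: tuple[str, ...]) -> np.ndarray:
    return np.array([[r[n] for n in names] for r in rows], dtype=np.float64)


def train_cascade(samples: "list[dict] | object", seed: int = 0) -> CascadeModel:
    """Train the two SVM stages from a labeled feature table.

    ``samples``: list of dicts (or a DataFrame) with the 6 feature columns
    plus ``label`` in {hemorrhage, vessel, background, residue}. Stage 1
    learns hemorrhage vs vessel on shape features; stage 2 hemorrhage vs
    background/residue on gray features. 5-fold CV accuracy is recorded.
    """
    import pandas as pd
    if isinstance(samples, pd.DataFrame):
        samples = samples.to_dict("records")
    pos = [s for s in samples if s["label"] == "hemorrhage"]
    ves = [s for s in samples if s["label"] == "vessel"]
    bg = [s for s in samples if s["label"] in ("background", "residue")]
    for name, grp in (("hemorrhage", pos), ("vessel", ves), ("background", bg)):
        if len(grp) < 5:
            raise ValueError(f"need >= 5 samples of class {name!r}")

    def fit_stage(neg: list[dict], names: tuple[str, ...]):
        X = _feature_matrix(pos + neg, names)
        y = np.array([1] * len(pos) + [0] * len(neg))
        clf = make_pipeline(StandardScaler(),
                            SVC(kernel="rbf", C=10.0, gamma="scale",
                                random_state=seed))
        folds = min(5, min(len(pos), len(neg)))
        cv = float(np.mean(cross_val_score(clf, X, y, cv=folds))) if folds >= 2 else float("nan")
        clf.fit(X, y)
        return clf, cv

    shape_clf, cv1 = fit_stage(ves, SHAPE_FEATURES)
    gray_clf, cv2 = fit_stage(bg, GRAY_FEATURES)
    return CascadeModel(shape_clf=shape_clf, gray_clf=gray_clf,
                        cv_accuracy=(cv1, cv2))


def classify_hemorrhages(cands: list[LesionCandidate],
                         model: CascadeModel) -> list[LesionCandidate]:
    """Run the cascade; survivors are labeled hemorrhages."""
    if not model.trained:
        raise ValueError("cascade model is not trained")
    if not cands:
        return []
    X1 = _feature_matrix([c.features for c in cands], SHAPE_FEATURES)
    keep1 = model.shape_clf.predict(X1) == 1
    stage1 = [c for c, k in zip(cands, keep1) if k]
    if not stage1:
        return []
    X2 = _feature_matrix([c.features for c in stage1], GRAY_FEATURES)
    keep2 = model.gray_clf.predict(X2) == 1
    out = [c for c, k in zip(stage1, keep2) if k]
    for c in out:
        c.kind = "hemorrhage"
    return out


def hemorrhage_candidates(enhanced: ChannelImage, green: ChannelImage,
                          vessels: BinaryMask,
                          od_mask: np.ndarray | None = None,
                          fov: np.ndarray | None = None,
                          cfg: PipelineConfig | None = None,
                          min_area: int | None = None,
                          max_area: int | None = None,
                          remove_vessel_overlap: bool = True
                          ) -> list[LesionCandidate]:
    """Background subtraction -> k-means -> vessel removal -> region growing
    -> feature extraction. Returns unclassified candidates.

    Size gates reflect the dotted-hemorrhage target: components at
    microaneurysm scale (below ~30 px at DRIVE resolution) and regions at
    macula scale (above ~1200 px) are not hemorrhage candidates.
    """
    cfg = cfg or PipelineConfig()
    px_scale = (enhanced.shape[1] / 565.0) ** 2
    if min_area is None:
        min_area = max(8, round(30 * px_scale))
    if max_area is None:
        max_area = round(1200 * px_scale)
    D = hemorrhage_background(enhanced, cfg)
    model, label_img = kmeans_segment(D, cfg.kmeans_k, cfg.seed)
    dark = darkest_cluster_mask(model, label_img, D)
    if fov is not None:
        dark &= ndimage.binary_erosion(fov, iterations=5)
    if od_mask is not None:
        dark &= ~od_mask
    cand_mask = BinaryMask(data=dark, label="candidate")
    if remove_vessel_overlap:
        cand_mask = remove_vessels(cand_mask, vessels)
    labels, n = ndimage.label(cand_mask.data, structure=np.ones((3, 3)))
    out = []
    for i in range(1, n + 1):
        comp = np.column_stack(np.nonzero(labels == i))
        if len(comp) < min_area:
            continue
        r0, c0 = comp[:, 0].min(), comp[:, 1].min()
        r1, c1 = comp[:, 0].max() + 1, comp[:, 1].max() + 1
        centroid = (float(comp[:, 0].mean()), float(comp[:, 1].mean()))
        seed = (int(round(centroid[0])), int(round(centroid[1])))
        grown = region_grow(green, seed, cfg.region_grow_t0,
                            bbox=(r0, c0, r1, c1),
                            area_cap=int(cfg.region_grow_cap * len(comp)))
        region = grown if len(grown) >= 4 else comp
        if len(region) > max_area:
            continue
        try:
            feats = extract_features(region, green)
        except ValueError:
            continue
        out.append(LesionCandidate(mask=region, centroid=centroid,
                                   features=feats, kind="hemorrhage",
                                   clipped=feats.pop("clipped")))
    return out


def detect_hemorrhages(enhanced: ChannelImage, green: ChannelImage,
                       vessels: BinaryMask, model: CascadeModel,
                       od_mask: np.ndarray | None = None,
                       fov: np.ndarray | None = None,
                       cfg: PipelineConfig | None = None) -> list[LesionCandidate]:
    cands = hemorrhage_candidates(enhanced, green, vessels, od_mask, fov, cfg)
    return classify_hemorrhages(cands, model)
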