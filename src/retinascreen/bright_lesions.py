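"""Hard-exudate detection.

Bright structure is isolated by opening-by-reconstruction background
estimation (erosion marker rebuilt under the image); edges of bright
objects are scored by the 8-template Kirsch compass operator; candidate
regions need both strong edges and residual brightness, the optic disc
is excluded, and a single-stage SVM on shape + gray + phase features
rejects soft-edged artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core_io import BinaryMask, ChannelImage, PipelineConfig
from .optic_disc import ODResult
from .red_lesions import LesionCandidate, extract_features
from .vessels import iterative_threshold

# the 8 classical Kirsch 3x3 compass templates (north, then rotations)
_KIRSCH_BASE = np.array([[5, 5, 5],
                         [-3, 0, -3],
                         [-3, -3, -3]], dtype=np.float64)


def _kirsch_templates() -> list[np.ndarray]:
    t = _KIRSCH_BASE
    out = []
    ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    vals = [t[i, j] for i, j in ring]
    for k in range(8):
        rot = np.zeros((3, 3))
        for idx, (i, j) in enumerate(ring):
            rot[i, j] = vals[(idx - k) % 8]
        out.append(rot)
    return out


KIRSCH_TEMPLATES = _kirsch_templates()


def background_morph(green: ChannelImage, se_radius: int | None = None,
                     cfg: PipelineConfig | None = None) -> ChannelImage:
    """Bright map B = green - opening-by-reconstruction background.

    The structuring-element radius must exceed the vessel width so the
    reconstruction flattens bright blobs but follows slow illumination.
    """
    cfg = cfg or PipelineConfig()
    if se_radius is None:
        se_radius = max(3, round(green.shape[1] * cfg.exu_se_radius_frac))
    marker = morphology.erosion(green.data, morphology.disk(se_radius))
    background = morphology.reconstruction(marker, green.data, method="dilation")
    bright = np.clip(green.data - background, 0.0, None)
    return ChannelImage(data=np.clip(bright, 0.0, 1.0), domain="difference")


def kirsch_edges(ch: ChannelImage | np.ndarray) -> np.ndarray:
    """Per-pixel maximum response over the 8 compass templates."""
    data = ch.data if isinstance(ch, ChannelImage) else np.asarray(ch, float)
    responses = [ndimage.correlate(data, t, mode="nearest")
                 for t in KIRSCH_TEMPLATES]
    return np.max(responses, axis=0)


def edge_strength_map(green: ChannelImage, sigma: float = 1.0) -> np.ndarray:
    """Kirsch edge strength on a lightly smoothed image, so sensor noise
    (which the compass templates amplify ~15x) does not drown lesion
    edges."""
    return kirsch_edges(ndimage.gaussian_filter(green.data, sigma))


def exudate_candidates(B: ChannelImage, edges: np.ndarray, od: ODResult | None,
                       fov: np.ndarray | None = None,
                       cfg: PipelineConfig | None = None,
                       pc_map: np.ndarray | None = None,
                       green: ChannelImage | None = None,
                       min_area: int = 6,
                       loose: bool = False) -> list[LesionCandidate]:
    """Threshold edge strength, close/fill to regions, keep bright ones,
    drop anything touching the dilated OD."""
    cfg = cfg or PipelineConfig()
    # the aperture rim is the strongest edge in the image; keep it out of
    # both the statistics and the candidate region
    valid = np.ones_like(edges, dtype=bool) if fov is None else \
        ndimage.binary_erosion(fov, iterations=8)
    pos_edges = edges[valid & (edges > 1e-9)]
    if pos_edges.size < 2 or np.ptp(pos_edges) == 0:
        return []
    t_edge = iterative_threshold(pos_edges)
    if loose:
        # training-harvest mode: admit soft-edged and dim structures so the
        # classifier sees realistic negatives
        t_edge *= 0.6
    strong = (edges >= t_edge) & valid
    regions = ndimage.binary_fill_holes(
        morphology.closing(strong, morphology.disk(2)))

    bright_vals = B.data[valid & (B.data > 1e-9)]
    t_bright = iterative_threshold(bright_vals) if (
        bright_vals.size >= 2 and np.ptp(bright_vals) > 0) else np.inf

    od_zone = None
    if od is not None:
        od_zone = ndimage.binary_dilation(
            od.mask.data, iterations=max(1, int(round(cfg.exu_od_dilation * od.radius))))

    ref = green if green is not None else B
    labels, n = ndimage.label(regions, structure=np.ones((3, 3)))
    out = []
    for i in range(1, n + 1):
        comp_mask = labels == i
        if comp_mask.sum() < min_area:
            continue
        if od_zone is not None and (comp_mask & od_zone).any():
            continue
        if float(B.data[comp_mask].mean()) < t_bright and not loose:
            continue
        # the closed/filled region overshoots the lesion; keep its bright core
        core = comp_mask & (B.data >= t_bright)
        if core.sum() >= min_area:
            comp_mask = core
        comp = np.column_stack(np.nonzero(comp_mask))
        try:
            feats = extract_features(comp, ChannelImage(
                data=np.clip(ref.data, 0, 1), domain="enhanced"))
        except ValueError:
            continue
        feats.pop("clipped", None)
        boundary = comp_mask & ~ndimage.binary_erosion(comp_mask)
        feats["edge_strength"] = float(edges[boundary].max()) if boundary.any() else 0.0
        feats["mean_b"] = float(B.data[comp_mask].mean())
        feats["pc_boundary"] = float(pc_map[boundary].mean()) \
            if (pc_map is not None and boundary.any()) else 0.0
        out.append(LesionCandidate(mask=comp,
                                   centroid=(float(comp[:, 0].mean()),
                                             float(comp[:, 1].mean())),
                                   features=feats, kind="exudate"))
    return out


EXUDATE_FEATURES = ("eccentricity", "circularity", "m_in", "m_d",
                    "edge_strength", "mean_b", "pc_boundary")


@dataclass
class ExudateModel:
    clf: object = None
    cv_accuracy: float = float("nan")

    @property
    def trained(self) -> bool:
        return self.clf is not None


def train_exudate_model(samples: list[dict], seed: int = 0) -> ExudateModel:
    """Single-stage RBF SVM: exudate vs everything else."""
    from sklearn.model_selection import cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    pos = [s for s in samples if s["label"] == "exudate"]
    neg = [s for s in samples if s["label"] != "exudate"]
    if len(pos) < 5 or len(neg) < 5:
        raise ValueError("need >= 5 samples per class")
    X = np.array([[s[f] for f in EXUDATE_FEATURES] for s in pos + neg])
    y = np.array([1] * len(pos) + [0] * len(neg))
    clf = make_pipeline(StandardScaler(),
                        SVC(kernel="rbf", C=10.0, gamma="scale",
                            random_state=seed))
    folds = min(5, min(len(pos), len(neg)))
    cv = float(np.mean(cross_val_score(clf, X, y, cv=folds))) if folds >= 2 else float("nan")
    clf.fit(X, y)
    return ExudateModel(clf=clf, cv_accuracy=cv)


def classify_exudates(cands: list[LesionCandidate],
                      model: ExudateModel) -> list[LesionCandidate]:
    if not model.trained:
        raise ValueError("exudate model is not trained")
    if not cands:
        return []
    X = np.array([[c.features[f] for f in EXUDATE_FEATURES] for c in cands])
    keep = model.clf.predict(X) == 1
    out = [c for c, k in zip(cands, keep) if k]
    for c in out:
        c.kind = "exudate"
    return out


def detect_exudates(green: ChannelImage, od: ODResult | None,
                    model: ExudateModel,
                    fov: np.ndarray | None = None,
                    cfg: PipelineConfig | None = None,
                    pc_map: np.ndarray | None = None) -> list[LesionCandidate]:
    cfg = cfg or PipelineConfig()
    B = background_morph(green, cfg=cfg)
    edges = edge_strength_map(green)
    cands = exudate_candidates(B, edges, od, fov, cfg, pc_map, green)
    return classify_exudates(cands, model)
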