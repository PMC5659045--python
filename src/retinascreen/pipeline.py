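"""End-to-end screening: enhancement, structure segmentation, lesion
detection, grading, optional 3-D export.

Each stage degrades gracefully: a failed stage is recorded in the report
and downstream stages that can proceed without it do so (e.g. hemorrhage
detection runs without a located macula; only the macular exclusion and
quadrant centering fall back).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .bright_lesions import ExudateModel, detect_exudates, train_exudate_model
from .core_io import FundusImage, PipelineConfig, green_channel, read_fundus
from .grading import grade_from_detections
from .macula import detect_macula
from .optic_disc import detect_od
from .phantom import make_exudate_table, make_training_table
from .preprocess import enhance
from .red_lesions import CascadeModel, detect_hemorrhages, detect_mas, train_cascade
from .vessels import segment_vessels


@dataclass
class Models:
    """Trained lesion classifiers; by default fitted once per process on
    phantom-derived feature tables."""
    cascade: CascadeModel
    exudate: ExudateModel


_MODEL_CACHE: dict[int, Models] = {}


def default_models(seed: int = 0, n_images: int = 10) -> Models:
    if seed not in _MODEL_CACHE:
        cascade = train_cascade(make_training_table(n_images, seed=seed), seed=seed)
        exu = train_exudate_model(make_exudate_table(n_images, seed=seed), seed=seed)
        _MODEL_CACHE[seed] = Models(cascade=cascade, exudate=exu)
    return _MODEL_CACHE[seed]


@dataclass
class ScreeningReport:
    source_id: str
    grade: str | None = None
    counts: dict = field(default_factory=dict)
    od: dict | None = None
    macula: dict | None = None
    lesions: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    stage_errors: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "grade": self.grade,
            "counts": self.counts,
            "od": self.od,
            "macula": self.macula,
            "lesions": self.lesions,
            "stage_seconds": self.stage_seconds,
            "stage_errors": self.stage_errors,
            "config": self.config,
            "version": self.version,
        }


def screen(image: "FundusImage | str", cfg: PipelineConfig | None = None,
           models: Models | None = None) -> ScreeningReport:
    """Run every stage in dependency order on one image."""
    cfg = cfg or PipelineConfig()
    img = read_fundus(image) if not isinstance(image, FundusImage) else image
    models = models or default_models(cfg.seed)
    report = ScreeningReport(source_id=img.source_id, config=cfg.to_dict())
    fov = img.field_of_view_mask

    def timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:   # noqa: BLE001 - stage degradation by design
            report.stage_errors[name] = f"{type(exc).__name__}: {exc}"
            out = None
        report.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        return out

    green = green_channel(img)
    enhanced = timed("preprocess", enhance, green, cfg, fov)
    vessels = timed("vessels", segment_vessels, green, enhanced, fov, cfg) \
        if enhanced is not None else None
    od = None
    if vessels is not None and len(vessels.skeleton):
        od = timed("optic_disc", detect_od, img, vessels.skeleton, cfg)
    od_mask = od.mask.data if od is not None else None
    od_center = od.center if od is not None else None
    od_radius = od.radius if od is not None else None
    mac = timed("macula", detect_macula, green, fov, od_center, od_radius, cfg)

    vmask = vessels.mask if vessels is not None else None
    mas = timed("microaneurysms", detect_mas, green, vmask, od_mask, fov, cfg) or []
    hems = []
    if enhanced is not None and vmask is not None:
        hems = timed("hemorrhages", detect_hemorrhages, enhanced, green, vmask,
                     models.cascade, od_mask, fov, cfg) or []
    exus = timed("exudates", detect_exudates, green, od, models.exudate,
                 fov, cfg) or []

    mac_center = mac.center if mac is not None else None
    grading = grade_from_detections(mas, hems, exus, mac_center, img.shape)

    report.grade = grading.grade
    report.counts = {**grading.counts,
                     "quadrant_hemorrhages": list(grading.quadrant_hemorrhages)}
    if od is not None:
        report.od = {"center": list(od.center), "radius": od.radius,
                     "low_confidence": od.low_confidence}
    if mac is not None:
        report.macula = {"center": list(mac.center),
                         "contour_score": mac.contour_score}
    report.lesions = {
        kind: [{"centroid": list(c.centroid),
                "area": int(len(c.mask)),
                "score": c.features.get("score")}
               for c in lst]
        for kind, lst in (("ma", mas), ("hemorrhage", hems), ("exudate", exus))
    }
    return report
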