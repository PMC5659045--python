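"""Image, mask and result I/O plus the shared domain types.

All internal grayscale processing uses float images in [0, 1]; 8-bit
conversion happens only at import/export. Coordinates are 0-based
(row, col) with row 0 at the top.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage


class FOVError(ValueError):
    """No usable field of view could be found in an image."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph with its circular aperture mask."""

    rgb: np.ndarray                      # H x W x 3 uint8
    field_of_view_mask: np.ndarray       # H x W bool
    source_id: str = ""
    pixel_size_hint: Optional[float] = None   # mm per pixel, if known

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        h, w = self.rgb.shape[:2]
        if h < 64 or w < 64:
            raise ValueError(f"image too small: {h}x{w}, need >= 64x64")
        self.field_of_view_mask = np.asarray(self.field_of_view_mask, dtype=bool)
        if self.field_of_view_mask.shape != (h, w):
            raise ValueError("FOV mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def fov_center(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.field_of_view_mask)
        return float(rows.mean()), float(cols.mean())

    def fov_radius(self) -> float:
        """Equivalent-area radius of the aperture."""
        return math.sqrt(self.field_of_view_mask.sum() / math.pi)


@dataclass
class ChannelImage:
    """A 2-D float intensity field in [0, 1]."""

    data: np.ndarray
    domain: str = "raw_green"   # raw_green | enhanced | background | difference

    _DOMAINS = ("raw_green", "enhanced", "background", "difference")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("ChannelImage data must be 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ChannelImage contains non-finite values")
        if self.domain not in self._DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        # difference images are signed; everything else lives in [0, 1]
        if self.domain != "difference":
            if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
                raise ValueError("ChannelImage values must lie in [0, 1]")
            self.data = np.clip(self.data, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A labelled boolean mask aligned with its source image."""

    data: np.ndarray
    label: str = "candidate"   # vessels | od | macula | ma | hemorrhage | exudate | candidate

    _LABELS = ("vessels", "od", "macula", "ma", "hemorrhage", "exudate", "candidate")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.label not in self._LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("empty confusion table")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults matching the published
    parameter values where those are printed and documented reconstructions
    elsewhere."""

    seed: int = 0

    # preprocess
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 2.0
    diffusion_iterations: int = 60
    diffusion_b: float = 0.02
    diffusion_l: float = 0.01
    diffusion_dt: float = 0.1

    # phase congruency
    pc_orientations: int = 8
    pc_scales: int = 3
    pc_wavelength_min: float = 3.0
    pc_scale_factor: float = 1.6
    pc_epsilon: float = 1e-5
    pc_noise_k: float = 2.0
    pc_sigma_onf: float = 0.55

    # vessels
    vessel_min_area: int = 30          # px at 565-px width, scaled by (W/565)^2
    vessel_ref_width: int = 565
    bottomhat_radius_frac: float = 1.0 / 40.0
    spur_length: int = 10

    # optic disc
    od_window_frac: float = 1.0 / 6.0  # sliding-window diameter / image width
    od_roi_frac: float = 1.0 / 3.0
    od_radius_frac_min: float = 1.0 / 14.0
    od_radius_frac_max: float = 1.0 / 10.0

    # macula
    macula_levels: int = 4
    macula_candidates: int = 10
    macula_rm_frac: float = 1.0 / 20.0
    macula_contour_levels: int = 5
    macula_od_exclusion: float = 1.2   # x OD radius

    # microaneurysms
    ma_window: int = 15
    ma_pc_wavelength_min: float = 2.0
    ma_score_range: tuple[int, int] = (20, 30)
    ma_score_min: int = 20
    ma_accept_mode: str = "threshold"  # "range" -> paper window; "threshold" -> score >= ma_score_min
    ma_h_min: float = 0.05
    ma_s_max: float = 0.02

    # hemorrhages
    hem_median_kernel: int = 80        # px at 1500-px width, scaled linearly
    hem_median_ref_width: int = 1500
    kmeans_k: int = 5
    region_grow_t0: float = 100.0 / 255.0
    region_grow_cap: float = 10.0      # x candidate area

    # exudates
    exu_se_radius_frac: float = 1.0 / 30.0
    exu_od_dilation: float = 0.2       # x OD radius

    # 3-D geometry defaults (mm / degrees)
    eye_ab: float = 25.0
    eye_bd: float = 24.0
    eye_alpha: float = 45.0

    def scaled_min_area(self, width: int) -> int:
        return max(1, round(self.vessel_min_area * (width / self.vessel_ref_width) ** 2))

    def scaled_median_kernel(self, width: int) -> int:
        k = round(self.hem_median_kernel * width / self.hem_median_ref_width)
        k = max(3, k)
        return k if k % 2 == 1 else k + 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clahe_tiles"] = list(self.clahe_tiles)
        d["ma_score_range"] = list(self.ma_score_range)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` config file; unknown keys are errors."""
        cfg = cls()
        names = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in names:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            cur = getattr(cfg, key)
            if isinstance(cur, tuple):
                value = tuple(type(cur[0])(p) for p in raw.replace(",", " ").split())
            elif isinstance(cur, bool):
                value = raw.lower() in ("1", "true", "yes")
            elif isinstance(cur, int):
                value = int(raw)
            elif isinstance(cur, float):
                value = float(raw)
            else:
                value = raw
            setattr(cfg, key, value)
        return cfg


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

FOV_LUMINANCE_THRESHOLD = 10.0 / 255.0


def estimate_fov(rgb: np.ndarray) -> np.ndarray:
    """Largest bright component of the luminance channel, hole-filled."""
    lum = rgb.astype(np.float64).mean(axis=2) / 255.0
    bright = lum > FOV_LUMINANCE_THRESHOLD
    if not bright.any():
        raise FOVError("no field of view found")
    labels, n = ndimage.label(bright)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def read_fundus(path: str | Path, source_id: str | None = None) -> FundusImage:
    """Load an 8-bit RGB raster and estimate its circular aperture."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("RGB", "L"):
                im = im.convert("RGB")
            if im.mode == "L":
                import warnings
                warnings.warn(f"{path.name}: grayscale input converted to RGB")
                im = im.convert("RGB")
            rgb = np.asarray(im, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode {path}: {exc}") from exc
    fov = estimate_fov(rgb)
    return FundusImage(rgb=rgb, field_of_view_mask=fov,
                       source_id=source_id or path.stem)


def write_fundus(img: FundusImage, path: str | Path) -> None:
    Image.fromarray(img.rgb, mode="RGB").save(path)


def green_channel(img: FundusImage) -> ChannelImage:
    """The green plane scaled to [0, 1] — the highest-contrast channel for
    retinal structure."""
    g = img.rgb[:, :, 1].astype(np.float64) / 255.0
    return ChannelImage(data=g, domain="raw_green")


def read_mask(path: str | Path, label: str = "candidate") -> BinaryMask:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return BinaryMask(data=arr > 127, label=label)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    Image.fromarray((mask.data * 255).astype(np.uint8), mode="L").save(path)


def write_channel(ch: ChannelImage, path: str | Path) -> None:
    data = ch.data
    if ch.domain == "difference":
        lo, hi = data.min(), data.max()
        data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    Image.fromarray(np.clip(np.round(data * 255), 0, 255).astype(np.uint8)).save(path)


def compute_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and overall accuracy.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(c.TP, c.TP + c.FN),
        "specificity": ratio(c.TN, c.TN + c.FP),
        "accuracy": ratio(c.TP + c.TN, c.TP + c.TN + c.FP + c.FN),
    }


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
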