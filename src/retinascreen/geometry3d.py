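"""Equivalent optical eye model and spherical back-projection.

The fundus camera images a cap of a sphere. From the camera working
distance AB, the eye axial length BD, the fundus-image height EF and the
field angle alpha, the model derives

    EC = EF / 2
    CD = AB + BD - EC * cot(alpha / 2)
    ED = sqrt(EC^2 + CD^2)
    beta = atan(EC / CD)
    R = ED / (2 cos beta)

and treats the imaged region as the spherical cap of radius R between
the rim point E and the deepest point D. The chord ED subtends a central
angle pi - 2*beta, which is the cap half-angle used for the equal-angular
pixel-to-sphere mapping: a pixel at radial fraction r of the field of
view maps to polar angle r * beta_cap at preserved azimuth, on the
sphere (x - g)^2 + (y - h)^2 + z^2 = R^2 centered above the image center
(g, h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import BinaryMask, FundusImage


@dataclass
class EyeGeometry:
    AB: float                  # camera working distance, mm
    BD: float                  # axial length, mm
    EF: float                  # fundus-image height, mm
    alpha: float               # field angle, degrees
    EC: float = field(init=False)
    CD: float = field(init=False)
    ED: float = field(init=False)
    beta: float = field(init=False)    # degrees
    R: float = field(init=False)       # sphere radius, mm
    beta_cap: float = field(init=False)  # cap half-angle, degrees
    g: float = 0.0             # sphere axis, image-plane x (mm)
    h: float = 0.0             # sphere axis, image-plane y (mm)
    theta: float = 90.0        # nominal cap half-angle bound, degrees

    def __post_init__(self) -> None:
        if min(self.AB, self.BD, self.EF) <= 0:
            raise ValueError("AB, BD and EF must be positive")
        if not 0.0 < self.alpha < 180.0:
            raise ValueError("alpha must be in (0, 180) degrees")
        a = math.radians(self.alpha)
        self.EC = 0.5 * self.EF
        self.CD = self.AB + self.BD - self.EC / math.tan(a / 2.0)
        if self.CD <= 0:
            raise ValueError("inconsistent camera geometry: CD <= 0")
        self.ED = math.hypot(self.EC, self.CD)
        beta_rad = math.atan(self.EC / self.CD)
        self.beta = math.degrees(beta_rad)
        self.R = self.ED / (2.0 * math.cos(beta_rad))
        self.beta_cap = math.degrees(math.pi - 2.0 * beta_rad)


def derive_geometry(AB: float, BD: float, EF: float, alpha: float) -> EyeGeometry:
    return EyeGeometry(AB=AB, BD=BD, EF=EF, alpha=alpha)


@dataclass
class SurfacePoint:
    x: float
    y: float
    z: float
    source_pixel: tuple[int, int]
    class_label: str = "fundus"


def _pixel_scale(img: FundusImage, geom: EyeGeometry) -> float:
    """mm per pixel so the FOV diameter spans EF."""
    return geom.EF / (2.0 * img.fov_radius())


def project_to_sphere(pixel: tuple[float, float], img: FundusImage,
                      geom: EyeGeometry, class_label: str = "fundus") -> SurfacePoint:
    """Map a FOV pixel onto the cap; raises outside the FOV."""
    r, c = int(round(pixel[0])), int(round(pixel[1]))
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]) or \
            not img.field_of_view_mask[r, c]:
        raise ValueError("pixel outside the field of view")
    cr, cc = img.fov_center()
    rad_px = img.fov_radius()
    dy = pixel[0] - cr
    dx = pixel[1] - cc
    frac = min(1.0, math.hypot(dy, dx) / rad_px)
    psi = math.atan2(dy, dx)
    phi = frac * math.radians(geom.beta_cap)
    x = geom.g + geom.R * math.sin(phi) * math.cos(psi)
    y = geom.h + geom.R * math.sin(phi) * math.sin(psi)
    z = -geom.R * math.cos(phi)
    return SurfacePoint(x=x, y=y, z=z, source_pixel=(r, c), class_label=class_label)


def unproject(point: SurfacePoint | tuple[float, float, float],
              img: FundusImage, geom: EyeGeometry) -> tuple[float, float]:
    """Inverse of project_to_sphere (round-trip within sub-pixel error)."""
    if isinstance(point, SurfacePoint):
        x, y, z = point.x, point.y, point.z
    else:
        x, y, z = point
    phi = math.acos(min(1.0, max(-1.0, -z / geom.R)))
    frac = phi / math.radians(geom.beta_cap)
    psi = math.atan2(y - geom.h, x - geom.g)
    cr, cc = img.fov_center()
    rad_px = img.fov_radius()
    return (cr + frac * rad_px * math.sin(psi),
            cc + frac * rad_px * math.cos(psi))


CLASS_COLORS = {
    "vessels": (220, 30, 30),
    "hemorrhage": (40, 60, 230),
    "exudate": (240, 220, 40),
    "ma": (255, 120, 0),
    "od": (255, 255, 255),
    "macula": (0, 255, 180),
}


def build_mesh(img: FundusImage, masks: list[BinaryMask],
               geom: EyeGeometry, stride: int = 4):
    """Tessellate the cap on a regular pixel grid with per-vertex color.

    Vertex colors are the source RGB overlaid with the class colors of any
    mask covering the pixel. Returns a trimesh.Trimesh.
    """
    import trimesh

    h, w = img.shape
    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    idx = -np.ones((len(rows), len(cols)), dtype=int)
    verts, colors = [], []
    cr, cc = img.fov_center()
    rad_px = img.fov_radius()
    beta_cap = math.radians(geom.beta_cap)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            if not img.field_of_view_mask[r, c]:
                continue
            dy, dx = r - cr, c - cc
            frac = min(1.0, math.hypot(dy, dx) / rad_px)
            psi = math.atan2(dy, dx)
            phi = frac * beta_cap
            verts.append((geom.g + geom.R * math.sin(phi) * math.cos(psi),
                          geom.h + geom.R * math.sin(phi) * math.sin(psi),
                          -geom.R * math.cos(phi)))
            color = tuple(int(v) for v in img.rgb[r, c])
            for m in masks:
                if m.data[r, c]:
                    color = CLASS_COLORS.get(m.label, color)
            colors.append(color + (255,))
            idx[i, j] = len(verts) - 1
    faces = []
    for i in range(len(rows) - 1):
        for j in range(len(cols) - 1):
            a, b = idx[i, j], idx[i, j + 1]
            c2, d = idx[i + 1, j], idx[i + 1, j + 1]
            if min(a, b, c2, d) >= 0:
                faces.append((a, b, d))
                faces.append((a, d, c2))
    mesh = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces),
                           vertex_colors=np.array(colors, dtype=np.uint8),
                           process=False)
    return mesh


def default_geometry(img: FundusImage, AB: float = 25.0, BD: float = 24.0,
                     alpha: float = 45.0) -> EyeGeometry:
    """Geometry from typical camera parameters when EF is unknown.

    EF is chosen so the fundus-image half-height subtends the field angle
    from half the camera-to-fundus distance (EC * cot(alpha/2) =
    (AB + BD) / 2), which keeps the derived geometry consistent (CD > 0)
    for any field angle.
    """
    ef = (AB + BD) * math.tan(math.radians(alpha) / 2.0)
    return EyeGeometry(AB=AB, BD=BD, EF=ef, alpha=alpha)
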