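"""Image-level NPDR severity from lesion counts.

Grades follow the International Council of Ophthalmology ladder,
restricted to the lesion types this system detects: no lesions -> no DR;
microaneurysms only -> mild; any hemorrhage or hard exudate -> moderate;
severe when hemorrhages are extensive (more than 20) in every one of the
four quadrants about the macula (the hemorrhage clause of the clinical
4-2-1 rule — venous beading and IRMA are not detected here and cannot
contribute).
"""

from __future__ import annotations

from dataclasses import dataclass

GRADES = ("no_dr", "mild", "moderate", "severe")
SEVERE_HEM_PER_QUADRANT = 20


@dataclass
class GradingResult:
    counts: dict
    quadrant_hemorrhages: tuple[int, int, int, int]
    grade: str

    @property
    def grade_index(self) -> int:
        return GRADES.index(self.grade)


def quadrant_counts(centroids: list[tuple[float, float]],
                    center: tuple[float, float]) -> tuple[int, int, int, int]:
    """Hemorrhage tallies per quadrant (NE, NW, SW, SE) about ``center``
    — the macula when located, else the image center."""
    q = [0, 0, 0, 0]
    r0, c0 = center
    for (r, c) in centroids:
        north = r < r0
        east = c >= c0
        if north and east:
            q[0] += 1
        elif north:
            q[1] += 1
        elif not east:
            q[2] += 1
        else:
            q[3] += 1
    return tuple(q)


def grade(n_ma: int, n_hem: int, n_exu: int,
          quadrant_hem: tuple[int, int, int, int] | None = None) -> GradingResult:
    """Apply the severity decision table to lesion counts."""
    for name, v in (("n_ma", n_ma), ("n_hem", n_hem), ("n_exu", n_exu)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if quadrant_hem is None:
        quadrant_hem = (n_hem, 0, 0, 0)
    if sum(quadrant_hem) != n_hem:
        raise ValueError("quadrant hemorrhage counts must sum to n_hem")
    if n_ma == 0 and n_hem == 0 and n_exu == 0:
        g = "no_dr"
    elif n_hem == 0 and n_exu == 0:
        g = "mild"
    elif all(qc > SEVERE_HEM_PER_QUADRANT for qc in quadrant_hem):
        g = "severe"
    else:
        g = "moderate"
    return GradingResult(counts={"n_ma": n_ma, "n_hem": n_hem, "n_exu": n_exu},
                         quadrant_hemorrhages=tuple(quadrant_hem), grade=g)


def grade_from_detections(mas: list, hemorrhages: list, exudates: list,
                          macula_center: tuple[float, float] | None,
                          img_shape: tuple[int, int]) -> GradingResult:
    center = macula_center if macula_center is not None else \
        (img_shape[0] / 2.0, img_shape[1] / 2.0)
    hem_centroids = [c.centroid for c in hemorrhages]
    q = quadrant_counts(hem_centroids, center)
    return grade(len(mas), len(hemorrhages), len(exudates), q)
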