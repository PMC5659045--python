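# Methods

This note records the models behind each stage, the defaults and why,
the numerical choices made where the published description was silent,
and what the synthetic phantom does and does not establish.

## Intensity and coordinate conventions

All grayscale processing happens on float images in [0, 1]; 8-bit
values appear only at import/export, and thresholds quoted on the 0–255
scale (e.g. the region-growing cut-off T0 = 100) are divided by 255.
Coordinates are 0-based (row, col) with row 0 at the top. The circular
aperture (field of view, FOV) is estimated as the largest connected
luminance component above 10/255, hole-filled; stages that compute
image statistics exclude a rim margin because the aperture boundary is
the strongest edge in any fundus photograph and would otherwise
dominate thresholds, window variances and edge statistics.

## Enhancement: CLAHE + coupled anisotropic diffusion

CLAHE runs on an 8 × 8 tile grid with clip factor 2.0 (neither value is
dictated by the source method; both are conventional and exposed in the
config). The coupled diffusion PDE is integrated by explicit Euler with
time step 0.1; gradients use central differences;
`|∇u| div(∇u/|∇u|)` is the standard mean-curvature form with the
squared-gradient denominator regularized by 1e−6. The auxiliary field v
receives the curvature term weighted by the schedule a_n (40 for
n ≤ 9; −0.7 per step for 10 ≤ n ≤ 55, giving a_55 = 7.8; halving from
n = 56, giving a_56 = 3.9 — at the overlapping index 55 the subtraction
branch is taken, being the more specific rule). Both fields are clamped
to [0, 1] each step; pixels outside the FOV are frozen. The default 60
iterations stop after a_n has collapsed, i.e. after v has frozen.
Edge-sensitivity constant l = 0.01 ("small"); coupling b = 0.02.

## Phase congruency

The log-Gabor bank uses 8 orientations × 3 scales, minimum wavelength
3 px, adjacent-scale factor 1.6, bandwidth ratio σ_onf = 0.55, angular
Gaussian spread with σ_θ = (π/8)/1.5. Each filter occupies a single
angular half-plane, so the complex inverse FFT directly yields the
even/odd quadrature pair. Local energy per orientation follows the
standard two-dimensional PC2 construction (projection of each scale's
response onto the mean phase direction minus the orthogonal
deviation).

Two quantities the source method names but does not define were
reconstructed:

* **Noise floor T_o** — the energy image's median is taken as the
  median of a Rayleigh distribution (valid because most of a fundus
  image is structure-free background), giving
  σ_R = median(E)/√(ln 4) and T_o = σ_R(√(π/2) + k·√((4−π)/2)) with
  k = 2. Calibrating on the energy image itself, rather than
  propagating an amplitude estimate from the smallest scale through an
  assumed inter-scale decay, makes the floor robust to the actual
  inter-scale correlation of the noise.
* **Weight W_o** — a sigmoid on the frequency spread
  (ΣA_s/max A_s − 1)/(s − 1), midpoint 0.15, gain 10. With only three
  scales, a wide vessel legitimately concentrates its response in the
  largest band, so the conventional midpoint of 0.5 (appropriate for
  4–6 scale banks) suppresses exactly the structures the bank is meant
  to find; 0.15 keeps the weight active only against single-bin
  spectral spikes.

The ⌊E − T⌋ operation is the positive part, the standard reading.

## Vessel segmentation

PC maps of the raw and the enhanced green channel are multiplied
pixel-wise and renormalized. Binarization applies the isodata fixed
point to the square root of the product: the product of two [0, 1]
maps lives on a compressed scale, and the geometric mean restores a
PC-scale quantity whose isodata split does not collapse onto the
strongest vessels. PC peaks on both walls of a vessel wider than the
smallest wavelength, so the binary map is closed with a disk of radius
3 and then gated by darkness: a vessel pixel must lie below a 15 × 15
median-filtered local background by at least 0.0125 (vessels are dark;
the closing halo is not). Components whose hole-filled shape has
compactness 4πA/P² above 0.5 are discarded — vessels are elongated, and
this removes rings left by lesion boundaries. Area filtering removes
components under 30 px at 565-px width, scaled by (W/565)².

The main-arcade skeleton intersects the vessel mask with the
bottom-hat response (disk radius W/40) re-thresholded by isodata,
thins it, prunes spurs under 10 px and keeps the largest component.

## Optic disc

A quadratic is fitted to the skeleton by centered normal equations in
both orientations (col-of-row and row-of-col). When the skeleton covers
only one arcade branch both fits can be plausible, so the stage scans
the region of interest around *each* candidate vertex (square of side
W/3, stride = window diameter/4) and keeps the global maximum of the
window response R = mean(LAB A) × population variance(HSI I), with
I = (R+G+B)/3. Windows must lie entirely inside the FOV — a window
straddling the black aperture rim has an enormous spurious variance.
The window diameter defaults to W/6, the middle of the stated 1/7–1/5
range. The boundary is the best circular Hough peak over radii
[W/14, W/10] on a gradient edge map (90th-percentile threshold) of the
green plane within 1.5 window diameters of the located center; a peak
below half the ideal accumulator falls back to a default-radius disc
flagged low-confidence.

## Macula

The à-trous dyadic wavelet with the quadratic-spline scaling filter
{1/8, 3/8, 3/8, 1/8} (taps spaced 2^(j−1) px at level j) provides the
coarse approximation at level 4; its regional minima inside the FOV,
excluding a zone of 1.2 OD radii around the disc, are the candidates
(10 darkest kept). Each candidate is scored on 5 iso-intensity levels
between the local window minimum and median (window half-size W/20):
score = mean over levels of concentricity/circularity, computed on a
σ = 1.5 px smoothed window because sensor noise makes the iso-lines of
the shallow macular dip ragged. The final selection weights the
contour score by the candidate's normalized depth in the coarse
approximation (weight 0.25 + 0.75·depth): the wavelet's size
selectivity makes the macula the darkest structure *at that scale*
(small deep lesions are attenuated), so the weight encodes "darkest
region with near-circular contours" and is what disambiguates the
fovea from a compact hemorrhage of similar raw darkness.

## Microaneurysms

Candidates are local maxima of the PC map of the inverted green
channel (λ_min = 2 px) above its isodata threshold, outside the dilated
vessel tree, the OD and the FOV rim. Each candidate's 15 × 15 window is
scanned along the eight published directions (0°, 22°, 45°, 66°, 90°,
111°, 135°, 156° — the printed, slightly non-uniform list is used
verbatim) by nearest-neighbor sampling with light binomial smoothing
({¼, ½, ¼}) so noise cannot mimic peaks. Seven criteria per direction
(gated by the first): significant central peak (prominence ≥ h_min =
0.05), strong peak (≥ 2 h_min), half-prominence width in [1, W/2],
left and right baseline slopes ≤ 0.02/px, centering within ±2 px,
shoulder symmetry ratio in [0.5, 2]. The score is the total over
directions, range 0–56. An ideal dot scores 56, which is why the
published closed acceptance window [20, 30] (inherited from a
reference method with a different score scale) is kept available but
the pipeline default accepts score ≥ 20; both modes are in the config.
Acceptances within 4 px merge into one detection.

## Hemorrhages

The difference image is the enhanced image minus a median background
(kernel 80 px at 1500-px image width, scaled linearly and forced odd —
31 px at DRIVE size). 1-D Lloyd k-means with K = 5 and quantile
initialization clusters the intensities; the objective is recorded
every iteration and asserted non-increasing. Clusters whose center
lies below mean − 0.5·std are candidate dark structure. Vessel removal
subtracts the 2-px-dilated vessel tree and drops components > 80%
explained by it. Components are size-gated to the dotted-hemorrhage
range: minimum 30 px and maximum 1200 px at 565-px width (scaled by
area) — below is microaneurysm scale, above is macula scale. Region
growing from each centroid accepts 8-neighbors with |f − m| < 100/255
(m = running region mean) and f below Otsu's threshold of a local
window (3× the candidate box), capped at 10× the candidate area. The
cascade is two RBF SVMs (C = 10, standardized features, 5-fold CV
reported): stage 1 separates hemorrhages from vessel fragments on
(eccentricity, circularity p²/4πa, axis ratio); stage 2 removes
background/residue on (m_in, m_out over a 2-px ring, m_d = m_out −
m_in). Training tables come from phantoms with vessel removal disabled
so vessel fragments appear, labeled by ≥ 50% ground-truth overlap.

## Hard exudates

Opening-by-reconstruction (erosion marker, disk radius W/30) gives a
background whose difference B isolates bright structure. Edge strength
is the maximum of the 8 Kirsch compass templates applied to a σ = 1 px
smoothed image (the templates amplify white noise ~15×, which would
otherwise bury lesion edges). Candidates need both a strong edge
(isodata threshold of in-FOV edge strengths) and residual brightness
(region mean B above the isodata threshold of B), minus anything
touching the OD dilated by 0.2 radii; each region is trimmed to its
bright core. A single RBF SVM classifies on shape (eccentricity,
circularity), gray (m_in, m_d), brightness, edge strength, and mean PC
on the boundary ("phase" feature). The training harvest runs with a
loosened gate (edge threshold × 0.6, no brightness requirement) so the
classifier sees realistic soft-edged negatives.

## Grading

no lesions → no DR; microaneurysms only → mild; any hemorrhage or
exudate → moderate; severe iff every quadrant about the macula (image
center if the macula was not located) holds more than 20 hemorrhages —
the hemorrhage clause of the clinical 4-2-1 rule, the only clause
applicable since venous beading and IRMA are not detected. Counts, not
areas, drive the grade.

## 3-D eye model

From working distance AB, axial length BD, fundus-image height EF and
field angle α: EC = EF/2, CD = AB + BD − EC·cot(α/2), ED = √(EC²+CD²),
β = atan(EC/CD), R = ED/(2 cos β). The chord ED subtends the central
angle π − 2β, taken as the cap half-angle; a pixel at radial fraction
r of the FOV maps to polar angle r·(π − 2β) at preserved azimuth on
the sphere (x−g)² + (y−h)² + z² = R², with the axis at the FOV center
and mm fixed by EF spanning the FOV diameter. The mapping is
invertible (round-trip < 0.5 px). When camera parameters are unknown
the defaults are AB = 25 mm, BD = 24 mm, α = 45°, and EF chosen so
EC·cot(α/2) = (AB+BD)/2, which keeps CD > 0 at any field angle. Meshes
are regular-grid tessellations of the cap with per-vertex RGB
(detection classes overlaid in fixed colors), exported as PLY.

## The phantom and what tests do (not) show

The generator emulates the image properties the stages rely on: a
circular aperture, a parabolic arcade whose vertex carries the bright
disc (within 15 px), vessels with flat-top cross-sections and crisp
walls whose width (2–7 px at DRIVE scale) correlates with depth
(15–30% of background, as main veins are darkest), an inverse-Gaussian
macula about 2.2 disc diameters temporal of the disc, dark MA dots
(radius 1–3 px, 15–40% contrast), irregular-boundary hemorrhage blots
(4–15 px, 15–40%), sharp-edged bright exudates (4–10 px, 20–50%
brighter), quadratic vignetting (12%) and Gaussian noise σ = 0.012 —
about three 8-bit levels, typical of a well-exposed fundus camera.

It does **not** model media opacity, uneven focal blur, laser scars,
nerve-fiber striation, the central light reflex of vessels, or
inter-camera color variation. Passing the phantom regression therefore
shows the pipeline implements the method correctly and is robust to
sensor noise and vignetting at realistic contrasts; it does not
certify clinical performance on hospital images, whose published
accuracies required the external databases.

## Problem sizes

Default test and acceptance runs use DRIVE-sized phantoms (565 × 584),
ten evaluation seeds, and classifier training tables harvested from
eight phantoms — sizes chosen so a complete from-scratch run finishes
in minutes on one CPU while every stage still operates at its native
resolution.

## Known limitations

* Wide, low-contrast vessels respond at the walls rather than the
  lumen; the closing/darkness-gate reconstruction recovers the band
  but slightly over-segments very thin capillaries.
* The hemorrhage stage targets dotted/blot hemorrhages; flame
  hemorrhages and lesions outside the 30–1200 px band are out of scope.
* Region growing uses a running mean, so the final region can contain
  a small fraction of pixels (< 5% asserted) violating the criterion
  against the final mean.
* The MA acceptance window [20, 30] from the source is inconsistent
  with this score reconstruction (an ideal dot scores 56); the
  threshold mode is the operative default, the window mode is retained
  for fidelity.
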