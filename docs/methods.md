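# Methods

`lesionfd` quantifies pigmented skin lesions photographed under paired
polarized (PL) and non-polarized (NPL) illumination: it segments the lesion,
measures its Euclidean geometry, estimates fractal dimensions of its shape
and of its pigment texture, and compares the measurements across diagnostic
groups (melanoma MM, dysplastic nevus DN, benign nevus BN). Because no
clinical image set ships with the package, a synthetic generator produces
both exact fractal fixtures and simulated lesion photographs; everything
below is exercised on those.

## Segmentation: divide blend with the tonal inverse

The grayscale photograph `I` (Rec. 709 luma from RGB, rounded half-up) is
divided by its own tonal inverse `M = 255 − I` using the raster-editor
division blend

    E(x, y) = I(x, y) · 256 / (M(x, y) + 1),

with the quotient truncated toward zero and clamped to [0, 255]. Substituting
`M` gives `E = 256·I/(256 − I)`, a strictly increasing tone curve with
`E(128) = 256` — every pixel at or above middle gray saturates to white while
darker pigment keeps contrast. Thresholding the blended image (default:
candidate lesion pixels strictly below 250), removing connected components
smaller than 1% of the largest, keeping the largest component and filling its
enclosed holes yields the lesion mask. The removal/keep/fill rule is a
deterministic replacement for erasing stray background artifacts by hand; all
three parameters are configurable and echoed into the output config. Cleanup
never alters the lesion body itself, only non-largest components.

## Morphometry

Area is the foreground pixel count times `mm_per_pixel²`. Perimeter is the
length of the marching-squares contour polygon simplified with
Douglas–Peucker at 1 px tolerance before summing segment lengths: the raw
marching-squares polyline overestimates smooth digitized boundaries by ~5%
(staircase bias), while the simplified polygon — vertices only where the
boundary genuinely turns, like a hand-drawn selection — measures a digitized
disc of radius 200 px to 0.1% and a 100-px square to 0.5%. The estimator
name is recorded in every result. Without calibration the values fall back
to pixel units with a logged warning.

## Intensity-difference box-counting fractal dimension

The image is tiled by square boxes of side ε anchored at the top-left
pixel. Each box contributes its intensity spread plus one,
`δI(i,j,ε) = max − min`, `I(ε) = Σ (δI + 1)`, and the fractal dimension is
the ordinary-least-squares slope of `ln I(ε)` against `ln (1/ε)`. The +1
keeps flat boxes counted, so a constant image has `I(ε) = (L/ε)²` and
FD = 2 exactly; a two-level depth-6 Sierpinski carpet measured at the
grid-aligned scales {3, 9, 27, 81, 243} has the closed-form sums
`I(3^k) = 256·8^(6−k) + (9^(6−k) − 8^(6−k))` and regresses to 1.8934,
against the theoretical log 8/log 3 = 1.8928. Both anchors are asserted in
the test suite and recomputed by `scripts/acceptance.py`.

Numerical choices:

* **Slope convention.** The estimator is the log–log regression slope.
  (Written as a ratio rather than a slope the defining limit is
  dimensionally inconsistent; the log–log reading is the standard one and
  is the only one that reproduces both fixture anchors.)
* **Partial edge boxes** are included with their actual pixels for
  power-series scales, so no pixel is discarded; block-series scales tile
  exactly by construction. Recorded in `FDResult.metadata`.
* **Grid anchoring.** A single top-left-anchored grid keeps the estimate
  deterministic. Averaging `I(ε)` over diagonal grid offsets is available
  behind `grid_offset_averaging` (default off).
* At least 3 distinct scales, each ≥ 2 px and ≤ half the smaller image
  dimension, are required; a zero-variance regressor is rejected.

Two scale-series schemes mirror the two analyses:

* **Power series** (shape FD): ε = 4, 16, 64, 256, … (base 2, exponent
  step 2) while ε ≤ min(dims)/4. Shape FD runs on the divide-blended
  image — dark lesion on saturated white — not on the binary mask, so
  border detail and marginal pigment gradients both enter.
* **Block series** (surface FD): all divisors ε of the ROI size with
  2 ≤ ε ≤ size/4, ascending, so every grid tiles the ROI exactly. For the
  450-px study ROI that is {2, 3, 5, 6, 9, 10, 15, 18, 25, 30, 45, 50, 75,
  90}; the divisor rule is a reasoned reconstruction of "grids calculated
  from the block size" and is flagged as such in the result scheme field.

On fractional-Brownian textures the estimator responds monotonically to
roughness: since `δI` per ε-box scales like `ε^H`, `I(ε) ∼ ε^(H−2)` and the
slope falls as the Hurst exponent rises — rougher texture (lower H), higher
FD. The tests assert the monotonicity, not a particular calibration.

## ROI extraction

Surface FD is computed on fixed-size square ROIs lying entirely within the
lesion mask. Placement is a greedy raster scan: every stride-1 candidate
origin is visited top-left to bottom-right and accepted iff its square is
fully inside the mask and overlaps no accepted ROI (implemented with an
integral image and a blocked-origin bitmap; an independent literal
double-loop oracle checks equivalence in the tests). The scan is
deterministic, honors non-overlap, and covers the lesion rather than a
hand-picked "characteristic" patch — avoiding selection bias by
construction. Lesions admitting no ROI are flagged and excluded from
surface analysis rather than failing. The study ROI size is 450 px; the
synthetic analyses use 64 px, matching the ~9× downscaling of the synthetic
frames.

## Statistics

Every variable is screened per group with Shapiro–Wilk at α = 0.05;
parametric tests are used only when all groups pass (groups with n < 3 or
zero variance force the nonparametric branch, logged). The branches:

| comparison | parametric | nonparametric |
|---|---|---|
| PL vs NPL (paired, per group) | paired Student t | Wilcoxon signed-rank |
| MM vs DN vs BN | one-way ANOVA + Fisher LSD | Kruskal–Wallis + Dunn mean-rank comparisons, Bonferroni-capped |
| MM in situ vs invasive | unpaired Student t | Mann–Whitney U |

Fisher LSD uses pooled-MSE pairwise t tests with N − k degrees of freedom
and no family-wise correction, exactly as the post hoc is named. The
rank-based post hoc is Dunn's z on joint-ranking mean ranks with the
standard tie correction, each two-sided p multiplied by the number of pairs
and capped at 1 — a reconstruction of "multiple comparisons of mean ranks"
as commercial packages report them (including the capped p = 1.000000
cells). Spearman correlations of shape FD against area and perimeter are
reported per group × illumination; groups under 5 lesions or tie-only
vectors are reported missing. Surface FD is compared at ROI level (n =
number of ROIs); a lesion-averaged alternative would avoid
pseudo-replication at the cost of discarding within-lesion variation, and
can be had by aggregating `surface_fd.csv` before calling the stats layer.
The paired stage excludes lesions missing either illumination, with a
logged warning; report assembly drops no record silently.

## Synthetic data generator

The generator replaces the undeposited clinical photographs. What it
emulates, and the defaults (all overridable per `SyntheticLesionParams`):

* **Canvas** 640 × 640 px, standing in for the study's 6000 × 4000 frames
  at roughly 1/9 scale (so the 64-px test ROI matches the 450-px study
  ROI proportionally).
* **Boundary**: radial Fourier series
  `r(θ) = R·(1 + A·Σ a_k cos(kθ + φ_k))`, `a_k = g_k/k` with seeded
  standard-normal `g_k` and uniform phases, 48 harmonics. The perturbation
  profile is normalised to unit peak, so the irregularity amplitude `A` is
  exactly the peak relative radial deviation and any `A < 1` yields a valid
  boundary; `A ≥ 1` (self-intersection) is rejected. The 1/k decay puts
  most energy in low-order lobes while the high harmonics carry
  irregularity into the scales the box-counting regression sees.
* **Texture**: fractional Brownian field by Fourier spectral synthesis
  (amplitude ∝ f^−(H+1), DC suppressed, unit variance), scaled to SD 18
  intensity levels around the lesion mean 70; background at mean 200 with
  SD 3 Gaussian noise. Lesion always darker than skin, enforced.
* **Paired illumination**: PL is the base render. NPL reuses the identical
  boundary and texture fields, pulls every pixel toward the background
  mean by the contrast factor 0.55, and overlays bright speckles on 0.2%
  of pixels — emulating the reflection and contrast loss that polarized
  imaging suppresses. PL and NPL of one seed therefore share the same true
  lesion mask.
* **Group presets** (border irregularity A, Hurst H, base radius px):
  BN 0.05/0.60/170, DN 0.15/0.50/180, MM 0.30/0.35/230, with study-design
  group sizes 54/23/20. These mirror the qualitative clinical ordering —
  benign lesions regular and fine-textured, melanomas large, ragged and
  coarse — and are calibration-free choices, not estimates of any patient
  population.
* **Reproducibility**: all randomness derives from one integer seed through
  named `SeedSequence` substreams (boundary, texture, background,
  speckle); per-lesion seeds derive from the cohort master seed, group
  label and index. Same seed, same bits.

What it does **not** emulate: hair, ulceration, specular sheen gradients,
vignetting, colour (the RGB variant is a fixed melanin-like tint of the
grayscale render), pigment networks, globules or regression structures, and
any empirical relationship between diagnosis and appearance beyond the
monotone preset ordering. Passing tests therefore demonstrate that the
pipeline recovers known generator parameters and known fixture dimensions —
they say nothing about diagnostic accuracy on real dermoscopy, which would
require the original photographs.

## Problem sizes

Unit tests run lesions on a 320-px canvas (radius 90, 24 harmonics) and
64-px ROIs; the parameter-recovery check uses two cohorts of 20 default
lesions; the power reconstruction draws 200 seeded replicates of three
normal groups at the published polarized shape-FD summary statistics
(1.3885/0.0404/20, 1.4225/0.0393/23, 1.4713/0.0579/54); the analysis
scripts simulate the full 97-lesion cohort. These sizes were chosen so the
whole suite exercises every stage end-to-end at desk scale.

## Known limitations

* The block-series grid rule and the mean-rank post hoc are reconstructions
  of under-documented commercial behaviour; both are flagged in output
  metadata and may differ in detail from the original software.
* Shape FD values depend on the lesion-to-frame ratio (the saturated
  background participates in the regression through the +1 term), so
  absolute values are comparable only across images of identical geometry —
  as in the study design, which fixed magnification and framing.
* The marching-squares + simplification perimeter is one of several
  defensible digitized-perimeter estimators; alternatives (Crofton,
  pixel-edge counting) differ by a few percent on smooth shapes.
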