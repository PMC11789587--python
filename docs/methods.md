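# Methods

## Gradient calibration model

Each gradient axis is characterised by a handful of measurements
(11 AFM points for wrinkle wavelength/amplitude, 5 nanomechanical-mapping
points for the DMT modulus, 5 sessile-drop points for the water contact
angle). Positions between knots are interpolated with a **monotone
piecewise-cubic (PCHIP)** interpolant: it is exact at every knot, preserves
the monotonicity of the physical gradients, and cannot overshoot between
sparse knots the way an unconstrained cubic can. Queries outside the knot
range are clamped to the end knots, because stitched-image edges can
overhang the characterised region.

Coordinate convention: origin at the sample corner where all gradients are
at their closed-mask end; x rightward, y upward, in mm; tiles indexed
(col, row) row-major with the tile **centre** used for parameter
assignment. A 20×20 mm sample tiled with 1742×1298 µm images gives an
11×15 grid (tiles whose centre falls outside the extent are dropped).

The scalar "topography" value used by all downstream models is the wrinkle
**wavelength** (µm); the amplitude is carried in the calibration tables but
not modelled, since the two co-vary tightly on these surfaces and heatmap
axes are conventionally labelled by wavelength.

Built-in default calibrations are placeholders spanning the characterised
ranges of the platform: wavelength 0–10 µm, DMT modulus 15–120 MPa, WCA
110→20°. Their position profiles are gently sigmoidal — a masked plasma
dose saturates at both mask ends — with deliberately different steepness
for stiffness (shallower) and wettability (sharper), since the two
treatments have distinct dose responses; this also keeps the S and W
columns of the co-varying T-S|W sample from being numerically collinear.
Fixed parameters default to WCA 22° on T-S (fully oxidised), 15 MPa on T-W
(base imprint stiffness), and flat topography (λ = 0) on S-W.

## Planted response model (synthetic screens)

The generator emulates the screen's qualitative biology with the simplest
monotone saturating forms:

* **Cell density** (cells mm⁻²):
  `d = [d_min + (d_max−d_min)·σ((w50−WCA)/τ)] · (1+γ_s·s̃) · (1+γ_t·t̃)`
  with σ the logistic function and s̃, t̃ the stiffness/topography min-max
  normalised to [−1, 1] over the screen-wide calibration ranges. Defaults:
  d_min = 50, d_max = 300 cells mm⁻², w50 = 70°, τ = 8°, γ_s = 0.2,
  γ_t = 0.05. Density is **not** gated by condition — fibroblasts adhere
  under all conditions.
* **Marker CTCF** (tile median, a.u.):
  `m = m_min + g(condition)·(m_max−m_min)·σ((w50−WCA)/τ)·(1−β_s+β_s·(s̃+1)/2)`
  with m_min = 5 000, m_max = 80 000 a.u., w50 = 55°, τ = 5°, β_s = 0.3.
  The logistic midpoint and width come from the observed hit structure
  (low hits confined to WCA > 60°, high hits to WCA < 50°). The condition
  gate g is 1 for 7 d TGF-β(+) and 0 otherwise, so gated conditions sit at
  the m_min baseline rather than at zero — the gate scales only the dynamic
  range. COL1 follows the α-SMA shape scaled by a configurable factor
  (default 0.6); the relative scaling is not quantified in the source data.

Per tile, the cell count is Poisson at the planted density × area; positions
come from a hard-core (dart-throwing) process with 25 µm minimum spacing;
per-cell marker totals are lognormal around the planted tile median with
CV = 0.35, so the sampled median is an unbiased anchor. Nucleus radii are
normal (6 ± 1 µm, clipped), cell radii 2.6× the nucleus radius.

### Rendering

Nuclei are rendered as 2D Gaussian spots, cell bodies as soft-edged disks
whose half-maximum sits exactly at the planted radius; each kernel is
normalised over its in-tile support so the planted per-cell total is
conserved to < 1 % before noise. Totals are expressed in a.u. = counts×µm²
and divided by the pixel area at render time, which makes downstream CTCF
estimates calibration-invariant. Per channel the renderer adds a constant
background with a smooth random linear gradient (±15 %), Gaussian PSF blur
(σ = 1 µm), Poisson shot noise, Gaussian read noise, and a camera offset,
then clips to 16 bits. Above ~12 expected photons the Poisson draw uses its
Gaussian approximation with the read noise folded into the same draw; below
that it is exact. Two RNG streams (population, optics) are split from a
per-tile seed derived by hashing (DOG, replicate, condition, col, row), so
identical seeds give byte-identical ground truth regardless of iteration
order, and the same population can be re-rendered under different noise.

The generator does **not** emulate cytoskeletal texture, stress-fiber
anisotropy, cell spreading changes, migration or cell–cell communication.
Passing tests therefore demonstrate that the pipeline recovers planted
densities and intensity medians under realistic optics — not that it would
segment unusually shaped or confluent real cells correctly.

## Segmentation and CTCF

Nuclei: Gaussian smoothing (2 µm), global Otsu threshold floored at
median + 5·MAD of the smoothed image (so a tile that is pure background
yields no objects instead of Otsu splitting the noise), hole filling,
h-maxima-seeded distance-transform watershed declumping applied to
connected components larger than the maximum nucleus area, then size
filtering to [20, 400] µm². Border-touching nuclei are excluded by default.
Objects above 5 000 µm² are removed as artefacts (survivors keep their
labels).

Cell bodies: one region per nucleus from a seeded watershed on the smoothed
sum of the marker channels, restricted to thresholded marker signal plus a
16 µm dilation of the nuclei. The dilated disk acts as a floor: where
marker signal is below threshold a cell still receives its dilation
neighbourhood (the fallback contract), and within the floor the faint
blurred rim of a bright cell stays with the cell rather than contaminating
the background estimate. Beyond the dilation radius cells may only claim
thresholded signal.

CTCF per cell and channel is `area(µm²)·mean − area(µm²)·background-mean`
with the background the mean over all non-cell pixels of the same tile and
channel; defining integrated density as area × mean makes the subtraction
dimensionally consistent, at the price that CTCF scales with the pixel-size
calibration (covered by a unit test). Negative CTCF values are kept —
clipping would bias tile medians upward on dim tiles. Tile density is
count/area; medians are recorded as missing when a tile has no cells.

## Assembly, hits, ROIs

Replicates are aligned by tile index (samples are cut and imaged
identically; no registration step) and averaged arithmetically per response
over non-missing values; medians are taken within tiles first, means across
replicates second. Missing tile medians propagate as missing, never as
zero. Fusion of the four DOGs into the 3D (T, S, W) cloud is plain
concatenation with provenance, no deduplication or rescaling.

Hits are ranked ascending with ties broken by (DOG, col, row) for
determinism. The extreme-group comparison defaults to Welch's
unequal-variance t-test (robust to the very different variances of the two
tails), with a two-way ANOVA (group × source DOG, Type II) available. ROI
cutpoints default to within-dataset tertiles of density and marker CTCF,
since no absolute thresholds exist for "low/intermediate/high"; explicit
cutpoints are accepted and always recorded alongside the classification.
Screen-vs-translation comparisons use a two-way ANOVA (source × ROI),
Šidák-adjusted Welch contrasts per ROI, and a one-way ANOVA with Tukey HSD
summarised as a compact-letter display (insert-and-absorb construction, so
two groups share a letter exactly when their adjusted p exceeds α).

## Importance models

**Random forest.** The mention of both a 75/25 held-out split and 10-fold
cross-validation is reconciled as: CV *inside* the 75 % training portion
selects among a small hyperparameter grid (min_samples_leaf ∈ {1, 4},
100 trees), the winner is refit on the full training portion, and R², MAE
and impurity importances (normalised to sum to 1) are recorded on the
untouched 25 %. The protocol repeats 100 times with reseeded splits
(seed = base + repeat) and reports mean ± sd. Permutation importance is
available as a cross-check flag. A constant target raises instead of
reporting an undefined R².

**PLS.** Per DOG, a PLS2 of the three responses on the three surface
parameters, all variables centred and scaled by their SD; a zero-SD column
(the DOG's fixed parameter) receives unit scale, entering with zero
variance and hence ≈0 importance instead of dividing by zero. The number
of components (1–3) minimises the leave-one-out RMSEP. Variable importance
per response is the standardised coefficient normalised by the sum of
absolute coefficients, ×100 — the only definition compatible with both
signedness and a 100 % total; VIP scores are unsigned and were rejected.
Although PLS2 fits the responses jointly, importances are reported per
response. Importance direction follows surface parameter → cell response.

## Problem sizes and numerical choices

Unit tests run on 256–700 µm tiles at 1 µm/px; the end-to-end screen checks
use the full 4-DOG, 11×15-tile geometry at 2 µm/px and reduced model
repeats (2–3), which the recovery experiments show is ample for the planted
effect sizes. `scripts/acceptance.py` runs the imaging pipeline at 1 µm/px.
Thresholds: detection matching radius 15 µm (≈ one cell radius); otsu
floors at 5 MAD-σ; watershed tie-breaks in signal-free zones by distance to
the nearest nucleus (weight 10⁻³, negligible against real signal).

## Known limitations

* The default calibrations are placeholders spanning the platform's
  published ranges, not measured tables; real screens should load their own
  calibration CSVs.
* The planted model treats stiffness and topography as multiplicative
  modulations of a wettability-driven logistic; it cannot represent
  interactions in which topography dominates locally.
* Density estimates ignore cells whose nucleus touches the tile border
  (≤ a few % of cells at these densities); no stitching or flat-field
  correction is performed.
* The PLS importance of two strongly co-varying predictors (the T-S|W
  sample) necessarily splits between them; its exact partition depends on
  the calibration profiles.
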