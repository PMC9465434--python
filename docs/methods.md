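# Methods

`doseqa` studies a question of experimental design in radiotherapy
pre-treatment quality assurance: *which input information lets a
convolutional classifier best identify mechanical delivery errors from 2D
dose comparisons?*  The package implements the whole chain — synthetic arc
plans, a surrogate portal-dose renderer, error injection, twelve
dose-comparison image operators, preprocessing, a small CNN, and a
factorial experiment harness — so that the comparison of input factors
(comparison method × normalization × resolution × classification level) can
be run end-to-end on a desk machine.

## Synthetic plans and the dose surrogate

Clinical plan cohorts and machine-fitted portal-dose prediction engines are
not public, so the study runs on synthetic stand-ins that preserve the
structure the classifier sees.

A plan is an ordered list of arcs; an arc is an ordered list of segments,
each holding per-leaf-pair MLC edge positions (bank A left, bank B right,
`a ≤ b`), a collimator angle and monitor units (MU).  `SimConfig` carries
the cohort parameters:

| parameter | VMAT-like | SBRT-like | meaning |
|---|---|---|---|
| `mu_mean` ± `mu_sd` | 333 ± 85 | 1746 ± 251 | per-arc MU, normal, floored at 1 MU |
| `target_field_size_mm` | 95 × 87 | 49 × 47 | union-aperture extent (x × y) |
| `grid_shape` | 160 × 160 | 112 × 112 | detector grid at 0.8 × 0.8 mm pitch |
| `penumbra_sigma_mm` | 2.0 | 2.0 | Gaussian penumbra sigma |
| `leaf_width_mm` | 5.0 | 5.0 | leaf-pair width (y) |
| `n_segments_per_arc` | 20 | 20 | control points per arc |
| `modulation_frac` | 0.25 | 0.25 | per-segment inward leaf jitter, fraction of field half-width |

Segment MU splits an arc's MU with symmetric-Dirichlet weights; leaf edges
jitter inward uniformly per segment, so the union aperture over a 20-segment
arc approximates the target field size.  The penumbra sigma of 2 mm gives an
80–20 edge width of ≈3.4 mm, typical of megavoltage portal dose at 100 cm
source–detector distance, and places the 10%-isodose crop boxes near
118 × 120 px (VMAT-like) and 63 × 68 px (SBRT-like) — the size regime the
preprocessing stage is designed around.

The renderer exploits that a segment aperture is a disjoint union of
per-leaf-pair rectangles: its isotropic 2D Gaussian blur is evaluated in
closed form as products of error-function edge profiles (exact continuous
penumbra sampled at pixel centres), scaled by MU, rotated by the collimator
angle (bilinear, about the grid centre) and summed over segments into one
time-integrated image per arc.  Dose is therefore exactly linear in MU, a
rectangular segment's cross-profile is an analytic erf edge, and rotating a
four-fold-symmetric aperture by 90° reproduces the unrotated image to
interpolation precision — all three are tested.  The surrogate deliberately
omits scatter, detector response, gantry/imager sag and measurement noise;
what it preserves is the geometry- and MU-dependence of the dose image,
which is what distinguishes the error classes.

Because errors are delivered and verified per arc, the dataset unit is the
arc: cohorts are flattened to single-arc delivery units.

## Error taxonomy and labels

Five mechanical error types perturb plan parameters:

| type | grid (zero excluded) | relevance threshold |
|---|---|---|
| collimator rotation | −2…+2° step 0.2° | 1° |
| MLC systematic | −2…+2 mm step 0.2 mm | 1 mm |
| MLC random | −2…+2 mm step 0.2 mm | 0.5 mm |
| MU systematic | −10…+10% step 1% | 5% |
| MU random | −10…+10% step 1% | 3% |

Systematic errors apply one magnitude to every segment of the arc.  Random
errors draw per-unit values (per segment for MU, per leaf for MLC) uniform
on `magnitude ± s` (s = 0.5 mm MLC, 2% MU) and record the realized signed
mean as the label magnitude — sweeping the target over the grid sweeps the
realized labels over the same range.  Level-1 labels are the five types;
Level-2 labels are binary relevant/irrelevant with an inclusive threshold
(`|m| ≥ t`), chosen because the grids contain the thresholds exactly; a
10-class joint (type × relevance) encoding is available by configuration.
The stricter random-error thresholds reflect that per-segment perturbations
partially average out in a time-integrated image while remaining clinically
meaningful.  Single-bank systematic MLC shifts move the bank in its
field-opening direction for positive magnitude (both-bank shifts translate
the aperture); leaf pairs driven past each other are clamped to zero gap
and logged.  There is no "no-error" class: magnitude 0 is excluded.

## Comparison operators

All operators take a reference (error-free) and an evaluated (with-error)
dose image on the same grid.  Dose normalization is global (relative to the
maximum reference dose).  Gamma and dose-difference maps are *signed* by
the local dose difference so over- and under-dosage stay distinguishable.

* **Gamma** (five criteria: 1%/1mm, 2%/2mm, 3%/3mm, 3%/1mm, 1%/3mm): per
  reference pixel, the minimum over evaluated positions within a search
  radius of 3 × DTA of `sqrt(dist²/dta² + ΔD²/δ²)`.  Candidate positions
  sit on a grid of pitch/`subsample_factor` (default 4) with bilinear dose
  interpolation; candidates are visited by increasing distance and the scan
  stops once the pure-distance term exceeds the current worst pixel, which
  cannot change the minimum.  An exhaustive per-pixel brute-force
  implementation exists solely as a test oracle, and the optimized path
  must match it to 1e-9.  No low-dose cutoff is applied inside gamma; the
  10% field crop handles low-dose regions.
* **Ratio**: eval/ref where ref ≥ 1e-3 × max(ref), neutral 1 elsewhere.
* **DD**: eval − ref (absolute) or (eval − ref)/max(ref) (relative).
* **DTA** (2 channels): per pixel, the signed distance to the nearest
  crossing of the linearly interpolated evaluated profile with the
  reference value, along the row (x) and column (y) separately; x is the
  column/horizontal direction.  If no crossing lies within W (half the
  axis extent) the value saturates at ±W, signed toward the closest dose
  approach.
* **DD/DTA** (3 channels): relative DD stacked with both DTA channels —
  the ingredients of gamma, unreduced.
* **SSIM**: sliding-window structural similarity,
  `((2μxμy+C1)(2σxy+C2)) / ((μx²+μy²+C1)(σx²+σy²+C2))`, uniform 11 × 11
  window, k1 = 0.01, k2 = 0.03, dynamic range = max(ref), population
  moments, symmetric padding; cross-checked against scikit-image.
* **Gradient** (2 channels): 3 × 3 Sobel magnitude and direction
  (`atan2`, radians, direction 0 at zero gradient) of the relative DD map.

Twelve variants total (5 gamma + 7 others).  On identical inputs every
method returns its neutral map (0, 1, or SSIM 1).

## Preprocessing

Comparison images are cropped to the bounding box of the *reference* dose
at a 10% low-dose threshold (the field is a dose concept; comparison images
can be signed), normalized, and resampled channel-wise to 32 × 32, 64 × 64
or 128 × 128 with bilinear interpolation (aspect ratio not preserved; the
anisotropic physical pixel pitch is reported as
`cropped_px × 0.8 mm / side`, truncated toward zero at one decimal).
Normalization statistics are per-channel pixel moments pooled over the
**training split only** and reused unchanged for validation and test:
min/max mode clips to mean ± 2·stdev and maps to [0, 1]; mean/stdev mode
standardizes without bounds.

## Classifier and training

The classifier is a block CNN — each block two 3 × 3 'same' convolutions
plus ReLU and a 2 × 2 max-pool, then dense layers and a softmax — written
directly on numpy (im2col forward, hand-derived backward, Adam).  That
keeps training bit-deterministic for a seed and lets the backward pass be
verified against finite differences.  The desk default is 2 blocks of
8/16 filters and one dense layer of 64 units, batch 32, learning rate 1e-3,
at most 30 epochs with early stopping on validation loss (patience 6, best
weights restored).

Datasets split 70/10/20 into train/validation/test, stratified by Level-1
class with largest-remainder rounding (per-class proportions within one
item; a 100-item balanced dataset splits exactly 70/10/20).  The test split
is consumed only by the accuracy evaluation; statistics, early stopping and
tuning see train/validation data only.

Hyperparameter search (optional, off by default at desk scale) minimizes
validation loss over {blocks, base filters, dense width, log-lr, batch
size}: a seeded random sampler, or a Bayesian variant that proposes by
expected improvement under a Gaussian-process surrogate after three random
warm-up trials, with median pruning of trials that trail the running median
validation loss at the same epoch.

## The factorial study

`enumerate_cells` crosses 2 levels × 12 methods × 2 normalizations × 3
resolutions = 144 cells.  All cells of a study share one image bank (plans,
reference and perturbed doses, comparison images, field crops are built
once per master seed and cached), so factor contrasts are never confounded
with sampling noise; every result row records the seeds and configuration
needed to regenerate it.  Per-cell failures are recorded and the study
continues.  Summaries report median/quartiles/extremes of accuracy per
factor and level; pairwise factor contrasts use a Wilcoxon rank-sum test
(a pragmatic in-package choice, not an attempt at a full multiplicity-
corrected procedure).

**Desk-scale study conditions.**  The default conditions were fixed once:
VMAT-like modality, single-arc units, the reduced magnitude grid (step
doubled, preserving the ±range), 5 error draws per arc and type.  The
classifier sanity study uses 25 arcs × 5 types × 5 draws = 625 balanced
images at 64 × 64 (relative DD, mean/stdev); the method-ranking study uses
8 arcs × 5 types × 3 draws = 120 images per master seed over three seeds,
with both methods reading the same bank per seed.  These sizes are the
package's chosen desk-scale operating point; the full 144-cell design at
larger cohort sizes runs through the same code path
(`enumerate_cells()` + `run_study`) in proportionally more time.

## What the synthetic study does and does not show

The generator emulates the *structure* of the clinical problem: arc plans
with realistic MU statistics and field sizes, per-segment modulation,
per-arc time-integrated dose, and error signatures that differ by type
(border signal for collimator rotation, leaf-edge signal for MLC errors,
field-wide scaling — smooth vs. textured — for systematic vs. random MU
errors).  It does not emulate measurement noise, scatter, detector
response, mechanical sag, patient anatomy, or the dose engine of any
specific linac.  Passing tests therefore demonstrate that the pipeline is
correct and that the comparative ranking of input factors is recoverable
under clean conditions; they do not certify absolute clinical accuracy
levels, which depend on data the package deliberately does not model.
Consistent with that scope, the acceptance checks assert bounds and
rankings (accuracy well above chance; simple dose-difference input at or
above DTA-only input across seeds) rather than absolute accuracy values.

## Numerical choices and degenerate inputs

* Gamma: the zero offset is always a candidate, so |γ| is bounded by the
  pure dose-difference gamma; offsets larger than the image are skipped;
  a zero-maximum reference is an error.
* DTA: float32 internals (distances at mm scale; halves memory traffic),
  rows processed in cache-sized chunks; exact dose ties resolve to the
  nearest exact-hit sample; flat-equal runs cross at their left sample.
* SSIM: window variances are clamped at zero against catastrophic
  cancellation; map values may exceed 1 by ≤1e-12.
* Resize: inputs already at target size are returned unchanged (bit
  identity); bilinear resampling never leaves the input value range.
* Pixel-pitch reporting truncates toward zero after rounding at 1e-6 to
  absorb float error (e.g. 68 × 0.8/32 = 1.7000…0002 → 1.7).
* Splitting requires ≥3 items per class; dataset statistics require ≥2
  images and nonzero variance.
* Training aborts with a diagnostic if the loss becomes non-finite;
  permuted-label controls are evaluated one-sided (see below).

A permuted-label control on the desk study lands far *below* the naive
per-image chance band: images cluster tightly by error type, so a model
trained on shuffled labels maps whole clusters to arbitrary labels and its
accuracy scatters at the cluster (class) level.  The control therefore
asserts the one-sided claim — permuted labels cannot beat chance — which is
the leakage test that matters.

## Known limitations

* The dose surrogate is fluence-like; absolute dose units are arbitrary.
* Leaf ends are ideal (no tongue-and-groove, no rounded-end transmission);
  closed leaves transmit nothing.
* DTA saturation at ±W makes the DTA channels heavy-tailed; no rescaling
  is applied beyond the study's normalizations.
* The desk-scale cohorts are small; per-cell accuracies carry sampling
  noise of several percentage points, which is why rankings are asserted
  across seeds rather than per run.
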