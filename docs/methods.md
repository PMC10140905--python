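# Methods

## Measurement model

The magnetization transfer ratio is computed pixel-wise as
`MTR = (M0 − MT)/M0`. Background is masked where `M0` falls below a
fraction (default 0.05) of the robust stack maximum (99th percentile of
`M0`); the original workflow this emulates does not document its handling
of air pixels, so the threshold is this package's choice. Valid MTR values
are not clipped to [0, 1]: at low SNR, noise can drive a small true MTR
slightly negative, and clipping would bias ROI means upward. Values in
[−0.5, 0) are retained; values outside [−0.5, 1] are treated as
non-physical and removed from the validity mask.

Regional statistics are arithmetic means over (ROI ∩ valid mask). Each
kidney region's mean is divided by the dorsal-muscle mean of the *same
slice*, and the per-slice normalized values are then averaged (unweighted)
across slices. Per-slice normalization was chosen over
pool-then-normalize because it also cancels slice-to-slice variation of
the saturation-efficiency field; on default phantoms the two orders agree
to well under 0.01 (tested). The muscle ROI is likewise taken per slice —
whether the emulated workflow drew it once per animal or per slice is not
documented.

Sham animals' two normal kidneys are averaged into a single per-subject
value per region, so the unit of analysis is the animal and group sizes
match the animal counts (6 normal, 9 stenotic, 9 contralateral). The
alternative (12 normal kidneys as independent observations) would
overstate the effective sample size.

## Segmentation

Cortex/medulla ROIs are estimated from a single anatomical reference
channel on which cortex is brighter than medulla and collecting-system
fluid is darkest (direction configurable). Within an operator-supplied
whole-kidney outline, the fixed order is: collecting-system exclusion
(own threshold, restricted to an interior-eroded mask so the cortical rim
cannot be mislabeled as fluid, and applied *first* so fluid pixels cannot
skew the parenchymal threshold), binarization (bright → cortex, dark →
medulla; Otsu within the kidney by default, manual override honored),
morphological opening of the cortex mask with a disk kernel (radius 2 by
default; removed pixels are reassigned to medulla), and extraction of the
cortex–medulla border (4-connectivity) as a QC overlay. The border is
display/QC output only; the MTR statistics use the filled ROIs. The auto
collecting-system threshold carries a bimodality guard (inter-mode gap
must exceed twice the summed within-mode spreads) so that kidneys without
a distinct fluid compartment are not split arbitrarily.

The dorsal-muscle reference is either a user-supplied freehand mask
(returned verbatim) or detected automatically as the largest foreground
component with a dorsal centroid, eroded by one pixel.

## Phantom

The generator emulates the study design: 9 RAS subjects (left kidney
stenotic, right contralateral) and 6 shams (two normal kidneys), imaged at
1.5 T and 3 T, 600 and 1000 Hz MT offsets, two timepoints, five coronal
128×128 slices (pixel spacing 2.34 mm for a 30 cm field of view).

* **Geometry.** Two elliptical-annulus kidneys (outer semi-axes ≈ 0.21 and
  0.13 of the matrix, medulla at 0.62 and collecting core at 0.28 of the
  outer axes, ≥ 2 px cortical rim), a dorsal muscle band, per-subject
  random jitter of centers (±2 % of matrix) and axes (±5 %), through-plane
  shrink of up to 15 % toward the outer slices. Simplicity is preferred
  over anatomical realism because the segmentation operators are purely
  intensity-based. Matrix sizes below 64 px cannot hold all structures and
  are rejected.
* **Contrast.** Tissue MT contrast is parameterized directly by the
  observed true MTR of each class — the study this emulates reports only
  MTR, so no two-pool Bloch–McConnell model is fitted. Kidney truths
  default to (published group-mean normalized MTR per field/offset
  stratum) × (muscle true MTR 0.40); collecting system 0.10 (fluid, low
  macromolecular content). The noiseless MT channel is
  `MT = M0·(1 − s·MTR_true)` with `M0 = 1` in all tissue, so the
  noiseless, uniform-`s` limit recovers truth to machine precision.
* **Between-subject variation.** One Gaussian draw per (subject, kidney,
  field, offset, region) with the stratum's published SD, clipped to
  [0.05, 2.2] in normalized units; the draw is shared across timepoints
  and timepoint 2 subtracts a configurable decrement (default 0.02 for
  normal kidneys only, emulating maturation of juvenile animals; 0 for
  stenotic/contralateral). Published SDs are treated as pure
  between-subject SDs, fully correlated across timepoints and independent
  across strata — the source data do not constrain the decomposition.
* **B1.** A multiplicative saturation-efficiency field
  `s(x,y) = 1 + a·g(x,y)` acts on the MT channel only (B1 bias enters MTR
  through saturation efficiency); `g` is a random 2-D polynomial of order
  2 normalized to max |g| = 1, so |s − 1| ≤ a everywhere (default
  a = 0.05). Coefficient scales are constant-dominant (1.0 / 0.2 / 0.1 per
  degree): transmit-gain miscalibration — a spatially flat multiplier — is
  the dominant inter-subject B1 effect in practice, and it is exactly the
  component that reference-region normalization removes. The win
  probability of normalized over raw estimates is
  (2/π)·arctan(σ_DC/σ_Δspatial), where σ_Δspatial is the SD of the
  kidney-minus-muscle difference of the spatial component; the chosen
  scales put the DC term ≈ 5× above that difference, so normalization
  wins in ~85–90 % of realizations (tested at ≥ 80 %).
* **Noise.** Rician magnitude noise, σ = tissue `M0` / SNR, applied
  independently to M0, MT and the anatomical channel; default SNR 40 at
  3 T and 20 at 1.5 T, reproducing the qualitatively noisier 1.5 T data of
  the emulated study. σ → 0 (SNR = ∞) gives the exact noiseless limit.
* **Determinism.** All randomness derives from the master seed through
  `numpy.random.SeedSequence` spawn keys over (subject, side, field,
  offset[, timepoint]), so identical spec + seed reproduce the dataset
  bit-for-bit and restricting the generated strata leaves the remaining
  draws unchanged.

What the phantom does **not** emulate: partial-volume mixing at tissue
boundaries, k-space/reconstruction effects, motion and respiration,
perfusion/T1-related confounds, patchy (focal) fibrosis, anatomical shape
variability, and the dual-weighting (T1 + T2\*) fusion of real anatomical
references (a single channel with the correct intensity ordering stands in
for it). Passing tests therefore demonstrate correctness of the analysis
chain and its statistical behaviour under the stated noise/bias model, not
segmentation robustness on real anatomy.

## Statistics

Group contrasts (normal/stenotic/contralateral, per region × field ×
offset at the first timepoint) use the two-sided Wilcoxon rank-sum test:
exact null by complete enumeration when the smaller arm has ≤ 8
observations and the pooled sample is tie-free, otherwise the normal
approximation with midranks, tie correction and continuity correction.
The ≤ 8 cutoff balances exactness against the combinatorial cost; at the
design's 9-vs-9 comparisons the approximation's empirical type-I error at
nominal 0.05 is ≈ 0.05 (tested within [0.03, 0.07]). Stenotic vs
contralateral enters with independent arms despite the within-animal
pairing, replicating the emulated analysis plan; the report notes this to
users. Field-strength (1.5 T vs 3 T) and test–retest (timepoint 1 vs 2)
comparisons use two-sided paired-samples t-tests matched by subject;
zero-variance difference vectors are a degenerate-input error, logged and
skipped by the grid. No multiple-testing correction is applied by default
(matching the emulated plan); `holm=True` attaches a Holm step-down
adjustment.

## Numerical and degenerate-input choices

* All-zero `M0` produces an empty-mask warning, not an error.
* A threshold that separates nothing yields a degenerate-segmentation
  warning with all parenchymal pixels assigned to the majority class.
* Empty (ROI ∩ valid) intersections raise errors naming region and slice;
  the per-acquisition loop logs and skips such slices as long as at least
  one slice survives per region.
* CSV outputs are written with fixed `%.12g` float formatting so repeated
  runs are byte-identical.
* Opening with radius 0 is the identity; cortex area is non-increasing in
  the kernel radius (tested).

## Problem sizes

Default analyses use the full study grid (15 subjects × 2 fields × 2
offsets × 2 timepoints, five 128×128 slices each; ≈ 7 s end to end on one
CPU). The power analysis of the stenotic-vs-contralateral cortex contrast
runs 200 full pipeline replicates of a cohort restricted to the stratum
under test (9 RAS subjects, 3 T/600 Hz, timepoint 1); the type-I
calibration uses 2000 draw-level replicates at n = 9 per arm. These sizes
were chosen to estimate the rates to within a few percent while keeping
the suite quick to run.

## Known limitations

* The phantom's anatomical channel is noiseless in structure (flat
  class-wise intensities plus Rician noise), which makes Otsu thresholds
  nearly ideal; real cortico-medullary contrast is spatially graded.
* Muscle auto-detection assumes a dorsal band disconnected from the
  kidneys; crowded anatomy requires the user-mask path.
* MTR is semi-quantitative: it depends on pulse parameters and residual
  B0/B1 effects that the muscle normalization only partially removes;
  bound-pool-fraction modeling is out of scope.
* The rank-sum power of the default 9-vs-9 design at the configured
  effect size is only ≈ 0.74, so single-cohort significance varies by
  seed — the acceptance suite tests the rate, not one realization.
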