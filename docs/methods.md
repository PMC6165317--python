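# Methods

This note records the models behind `shadematch`, the parameter choices
that matter, and what the synthetic data does and does not emulate.

## Color model

Camera RGB is treated as unit-scaled reflectance (8-bit channels / 255) and
converted **without gamma linearisation** straight through the
sRGB-primaries/D65 matrix, with the white-point division folded in so that
white maps to XYZ = (1, 1, 1) and hence L\* = 100. The Lab transfer
function uses the classical cube-root branch above t = 0.008856 and the
linear branch 7.787·t + 16/116 below it; the branches agree to < 10⁻³ at
the junction. An optional flag enables sRGB gamma decoding before the
matrix, and another clamps L\* to [0, 100]; both default off, so raw values
are reported. Whether an intraoral camera's RGB is gamma-encoded is a
convention choice, not something the arithmetic can decide; the package
commits to the no-gamma reading and keeps the flag for the other one.

The inverse (Lab → RGB), used by the simulator, inverts the same two stages
in closed form — branchwise inversion of f, then the matrix inverse — so the
round trip is self-consistent to machine precision rather than depending on
an external colorimetry convention.

ΔE is the plain Euclidean norm in (L\*, a\*, b\*). CIEDE2000/CIE94 are out
of scope.

## Calibration

The correction model is a pure 3×3 linear map fitted per output channel by
least squares on the five chart colors (an affine 3×4 variant exists behind
a flag, default off). Two consequences shape everything downstream:

- a 3×3 map cannot remove an additive bias, so simulated device bias
  survives correction and is the main *systematic* inter-device residual;
- the five tooth-range chart colors are nearly collinear in RGB (condition
  number ≈ 400), so noise in the chart measurement is strongly amplified
  into the fitted matrix. Because the physical chart is captured under a
  fixed jig and averaged over the whole patch, the simulator models chart
  readings with one tenth of the run-time measurement noise
  (`chart_noise_factor = 0.1` in `calibrate_device`).

Fitting is on the five mean chart colors, not per-pixel data. Rank-deficient
measured sets raise an error; a minimum-norm solution with a logged warning
covers the remaining degeneracies.

## Segmentation

Stages and their knobs (all exposed as keyword arguments):

- grayscale `G − |R − G|`, clamped below at 0 (8-bit output); the blue
  channel plays no role.
- Canny with hysteresis thresholds (low, high) = (10, 20) in 8-bit gray
  units and Gaussian σ = 1. The two-number parameterisation is read as
  hysteresis thresholds because that is the only two-number Canny knob;
  both are configurable.
- Morphological closing (one 3×3 dilation, then one erosion) seals
  single-pixel edge gaps; order and element size configurable. The closing
  never removes detected edge pixels.
- Binarisation threshold = mean gray over the **edge area**, taken as the
  one-pixel (3×3-dilated) band around the detected edge lines. The band
  straddles both sides of each boundary, so the threshold lands strictly
  between region and surround even on noiseless fixtures, where the thinned
  Canny line itself sits wholly on the brighter side and its own mean would
  equal the region gray exactly.
- 8-connected component labeling; the selected component is the one whose
  centroid is nearest the image center, subject to an area floor of 1% of
  the frame (the tab fills a large central fraction of the field of view);
  ties break by larger area, then smaller label.
- The region's channel-wise mean RGB is the measurement. An optional
  percentile clip on in-region brightness (`glare_exclude`) drops residual
  specular pixels before averaging; default off, since glare suppression is
  primarily the hardware's job.

The pipeline is deterministic: identical input bytes give identical masks
and colors.

## Shade database and matching

Measurements are (device, repeat, tab) → mean Lab records; the per-tab
representative is the unweighted mean pooled over all devices and repeats
(identical to device-equal weighting for balanced designs; a median mode
exists behind a flag). Features for the classifiers are the raw Lab
triples — Lab axes are commensurate, so no scaling is applied by default.

The SVM uses an RBF kernel with one-vs-one multiclass reduction; with no
explicit hyperparameters, C and γ are chosen by 5-fold grid search over
C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1, 10} on the training set with a
fixed seed. Comparison classifiers: multinomial L2 logistic regression,
100-tree random forest (seeded), k-NN with k = 5. Euclidean ties on exactly
equal distances break by canonical 1M1 → 5M3 label order (a
probability-zero event on continuous data, logged when it fires).

## Evaluation conventions

- Matching rate: 100 × matched/26; unrounded values live on the k/26 grid.
- Run summaries: mean rounded to one decimal; **sample** SD (n − 1) on the
  unrounded fractional rates. One-decimal table entries are first snapped
  back to the nearest k/26 grid point; this is what makes a summary
  recomputed from a printed table agree with one computed from raw counts
  (the snapped convention yields 4.46 where the rounded-value SD gives 4.45
  on the same row).
- Reliability: per-tab modal-prediction frequency × 100, correctness
  ignored; overall = mean over tabs; modal ties take the canonically first
  label and are logged.
- "Failure rate" is a dispersion statistic whose precise reading is
  ambiguous in common usage, so both are computed: the SD of per-run
  agreement with the modal predictions (`mode="run"`) and the SD of the
  per-tab reliabilities (`mode="tab"`).
- LPOCV enumerates all C(N, p) validation subsets (N = 8, p = 3 → 56
  splits; every device validated C(7, 2) = 21 times). A split's accuracy
  averages the per-device accuracies of its held-out devices (pooling all
  held-out records is available via a flag); the reported SD is across
  splits.

## Synthetic data: what it emulates, and what it does not

**Palette.** The 26 tab colors are generated, not measured: L\* = 84 − 5·group
(≈ 79 down to ≈ 59, the lightness range of natural teeth), b\* = 8 +
7·(chroma − 1), a\* offset −4.5 / 0 / +4.5 for the L/M/R hue variants, plus
a small seeded jitter. Adjacent tabs end up ΔE ≈ 5–7 apart, the spacing
colorimetric surveys report for the physical guide. The palette is
version-tagged so nothing treats it as VITA ground truth.

**Devices.** Each simulated camera applies a near-identity 3×3 distortion
(entries within ±10%), a small RGB bias (default ±0.005 — deliberately
modest, because a 3×3 CCM cannot remove it), and per-channel Gaussian noise
(default σ = 0.01 in unit-RGB terms, roughly ΔE 1–2 per measurement for
tooth colors). On top, an **anisotropic Lab perturbation** along one
direction shared by the whole device family (stretch 3× the baseline Lab
noise, using the conversion's local Jacobian scale of ≈ 60 Lab units per
unit RGB σ) emulates correlated inter-device variation that survives
correction; the shared direction is what elongates the pooled per-tab
clusters and opens the gap between nearest-mean and SVM matching. Under
these defaults both matchers score between roughly 70% and 90% — stressed
but functional — with the SVM ahead on average.

**Scenes.** Rendered frames are flat-painted rectangles plus Gaussian pixel
noise: a red-dominant gum band, a dark background whose `G − |R − G|` value
is close to the gum's (a real mouth cavity is dark and largely free of
green-dominant structures), optional neighbor teeth painted a slightly
offset shade of the central tab, and an optional channel-saturated glare
disc. Ground-truth masks come with every render.

**Not emulated:** translucency and fluorescence, surface curvature and
shading gradients, positioning error, photon/shot noise statistics, real
VITA spectra, and real intraoral texture. Passing tests therefore show the
*algorithms* behave as specified under a controlled generative model — they
do not certify clinical accuracy on real teeth, and the published per-device
accuracy figures of physical units are outside what desk-scale simulation
can reproduce.

## Problem sizes

The test suite and examples run the protocol at its native size (8 devices,
26 tabs, 7 repeats, 10 runs; 56 LPOCV splits). The SVM-vs-Euclidean
benchmark uses 20 independent replicates of the full 8-device family with
one full-guide run per test device; the noise-degradation check uses 5
replicates per noise level with common random numbers across levels to
reduce comparison variance. The LPOCV example uses 2 repeats per device to
keep the 4-classifier × 56-split enumeration brisk; the structure of the
enumeration is independent of the repeat count.

## Known limitations

- The no-gamma RGB convention makes tooth colors darker in RGB than an
  sRGB-encoded photo would be; all stages are self-consistent, but absolute
  Lab values are not comparable to spectrophotometer readings.
- The CCM chart's near-collinearity is intrinsic to tooth-range
  calibration; with noisier chart captures than modeled the correction can
  do more harm than good.
- The grid-searched SVM refits 80 models; for bulk simulation pass explicit
  `{"C": 10, "gamma": 0.1}` (the grid's usual winner on this data) to skip
  the search.
- Reliability and failure-rate conventions follow the definitions above;
  other groups may report the same words with different arithmetic.
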