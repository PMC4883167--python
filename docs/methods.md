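# Methods

`eegtexture` classifies single-channel EEG segments as normal or epileptic
seizure by treating the log-power spectrogram as an 8-bit image, cutting it
into the five conventional rhythm bands, and describing each band's texture
with one of three descriptor families before a max-margin classifier.

## Time–frequency representation

A segment x[m] is framed with a Hann window (default length 128, overlap
64), each frame zero-padded to N = 256 and transformed,

    X(n, k) = Σ_m x[m] w[n − m] e^{−j2πkm/N},    S(n, k) = log |X(n, k)|²,

on the one-sided grid f_k = k·fs/N, k = 0…N/2. The defaults assume the
common public-dataset geometry of 4097 samples over 23.6 s, i.e.
fs = 4097/23.6 ≈ 173.61 Hz, giving 63 frames and ≈ 0.678 Hz bins. Those
window parameters are this package's choice: they are the coarsest standard
dyadic setting for which every rhythm band spans at least five frequency
rows, the minimum for the 3×3 texture operators to produce a usable interior.
Zero power is floored at 10⁻¹² × max power before the log (an all-zero
signal floors at 10⁻¹² absolute), so S is always finite. The log base is
natural; only relative levels survive the 8-bit quantization that follows.

Each spectrogram is independently min–max mapped onto {0,…,255} with
half-away-from-zero rounding; a constant spectrogram maps to all zeros by
convention. Per-image (rather than per-dataset) normalization mirrors
converting each t–f image to an 8-bit gray-scale image on its own; it also
makes the descriptors insensitive to overall signal gain except through
re-quantization. Rows are then partitioned into half-open bands — delta
[0, 4), theta [4, 8), alpha [8, 12), beta [12, 30), gamma [30, 50) Hz — and
rows at or above 50 Hz are discarded. Internally, row index increases with
frequency; no consumer depends on the orientation.

## Texture descriptors

**GLCM.** Co-occurrence counts at distance δ = 1 and the four angles 0°,
45°, 90°, 135° (offset vectors (0,δ), (−δ,δ), (−δ,0), (−δ,−δ)), counted
asymmetrically exactly as the directional definition states, with
out-of-image pairs skipped. The full 8-bit range L = 256 is kept — no
gray-level reduction, which at these image sizes costs nothing. Per matrix
(normalized to P) the four standard statistics are contrast Σ(p−q)²P,
correlation Σ(p−μ_p)(q−μ_q)P/(σ_pσ_q) from the marginal moments (defined as
0 when either marginal SD vanishes), energy ΣP², and homogeneity
Σ P/(1+|p−q|). Features are concatenated per angle, not averaged: 4 angles
× 4 statistics = 16 per band, 80 per signal.

**TFCM.** The texture feature coding method quantizes, for every interior
pixel, the neighbour-minus-centre differences of the four 3×3 connectivity
sets (horizontal, vertical, two diagonals) at a tolerance Δ (default 80
gray levels) into {−1, 0, +1}, maps each 2-vector to a variation class
1–4 (flat / single change / monotone slope / ridge-valley), combines the
two first-order classes and the two diagonal classes through the ranked
unordered-pair index (1…10 over the pairs 11, 12, 13, 14, 22, 23, 24, 33,
34, 44), and composes the texture feature number TFN = (a₁−1)·10 + (a₂−1)
∈ [0, 99]. The class table and two-level composition are a fixed variant
chosen by this package: the method's defining properties — tolerance
quantization, "degree of variation" ordering, first-order/diagonal
composition — admit several concrete tables, and fixing one keeps results
reproducible. Borders are excluded so all four connectivity sets exist. The
12 statistics comprise four histogram terms (mean convergence, code
variance, code entropy in bits, uniformity), four moments of the
direction-averaged TFN co-occurrence matrix at distance 1 (first/second
difference and inverse-difference moments), and the four per-direction
co-occurrence energies; 12 per band, 60 per signal. The TFN image must be
at least 2×2 so every co-occurrence direction has a pixel pair; in the
pipeline the smallest band yields a 4×61 TFN image.

**LBP.** The 3×3 local binary pattern with neighbours indexed clockwise
from the top-left corner, threshold f(t) = 1 for t ≥ 0 (so a constant block
codes to 255), weights 2^(i−1). Any fixed neighbour ordering gives the same
histogram up to a relabelling of codes, so the ordering is simply fixed.
The feature is the raw 256-bin count histogram of the interior codes —
normalization is left to the classifier's scaling stage; 256 per band,
1280 per signal.

Band order in every concatenated vector is delta → gamma (low to high).

## Classification and evaluation

Two solver families, both backed by scikit-learn:

* kernel SVM (`SVC`) with linear, polynomial (degree 3, coef0 = 1, scaled
  gamma — unstated in the original experiments, so standard defaults), or
  histogram intersection k(x,y) = Σ min(x_d, y_d) as a precomputed kernel;
* LIBLINEAR-style primal linear SVM (`LinearSVC`, squared-hinge loss, L2 or
  L1 penalty, dual=False). The stopping tolerance is 10⁻³ — between
  LIBLINEAR's own default of 10⁻² and scikit-learn's 10⁻⁴ — so the L1 runs
  at large C converge without an excessive iteration budget.

Min–max scaling to [0, 1] (fit on training folds only, test folds clipped
into the range) is on by default: the chi² map and the intersection kernel
need nonnegative inputs, and GLCM correlation can be negative.

The homogeneous chi² feature map expands each nonnegative component into
2n+1 values using the closed-form kernel signature κ(λ) = sech(πλ):
√(xL), and √(2xL κ(jL))·(cos, sin)(jL log x) for j = 1…n. The default is
order n = 1 with period L = 0.65, the common practice for this map; when a
period is not supplied at higher orders, it is solved so the map reproduces
k(x, x) exactly (the approximation error then falls with order). Zero
components map to zeros.

Named presets ship the published experimental settings: GLCM — linear SVM
C = 100, LIBLINEAR L2-reg L2-loss C = 0.07, and chi²-map + LIBLINEAR;
TFCM — polynomial SVM C = 1, LIBLINEAR L1-reg L2-loss C = 15 (± the map);
LBP — intersection SVM C = 0.32, LIBLINEAR L1-reg L2-loss C = 100 (± the
map).

Evaluation uses stratified, seeded, shuffled fivefold cross-validation.
Whether the original folds were stratified is unstated; stratification with
an explicit seed is the reproducible choice. Confusion counts are pooled
over folds (rather than averaging per-fold metrics) and reported in percent:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total,
with seizure the positive class.

## Synthetic data

The generator emulates only the statistical contrast the method exploits:
the normal class is unit-RMS 1/f-shaped Gaussian noise (flat below 1 Hz)
plus a ~10 Hz alpha sinusoid of amplitude ≈ 1.4 with random phase and ±15%
amplitude jitter; the seizure class is a 3.5 Hz spike-wave — fundamental
plus 2nd/3rd harmonics, sharpened by a signed power-law |·|^0.7 — with 10%
added pink noise, frequency jittered ±5%, scaled to 5× the mean normal RMS
(±10% per signal). Defaults: 4097 samples at 173.61 Hz, matching the
segment geometry above.

What this does and does not show: the two classes differ in rhythm-band
energy placement and amplitude, so the spectrogram textures are strongly
class-separated and the GLCM/LBP presets reach ~100% fivefold CV accuracy,
with TFCM in the 80–90% range. That validates the plumbing — every stage
from STFT to pooled metrics — and the ordering of descriptor families, but
not performance on real EEG: the generator has no artifacts (eye-blink,
EMG), no non-stationary background, no inter-subject variability, and its
classes are separable by construction. Amplitudes stay floating point; no
integer ADC quantization is applied, since the descriptors act on the
quantized t–f image, not raw amplitudes.

## Numerical choices and degenerate inputs

* Log floor 10⁻¹² × max power; natural log.
* Gray quantization rounds half away from zero; constant image → all zeros.
* GLCM of an image too small for the offset returns an all-zero matrix with
  a warning; statistics of an all-zero matrix raise instead of returning
  NaNs. Correlation of a constant image is 0 by convention.
* TFCM with Δ → ∞ collapses every class to 1 and yields the degenerate
  feature vector (0, 0, 0, 1, 0, 1, 0, 1, 1, 1, 1, 1).
* Images below 3×3 are rejected by the 3×3 operators (no padding is ever
  applied; interiors shrink by one pixel per side).
* Problem sizes in the shipped evaluation: 100 signals per class, fivefold
  CV; oracle suites run on ≥100 random 9×11–16×16 images.

## Known limitations

* The TFCM code tables are a documented variant (see above); numeric TFCM
  features are not bit-comparable to other TFCM implementations, though the
  12 statistics' definitions are.
* STFT window type/length/overlap for the original experiments are unknown;
  results depend on them through band row counts.
* Only binary normal/seizure classification is supported; no multiclass,
  hyperparameter search, or probability calibration.
* The optional dataset-directory adapter expects single-column ASCII files;
  EDF/BDF and multi-channel montages are out of scope.
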