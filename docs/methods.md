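# Methods

## Scope and data model

`frostspec` grades individual corn-seed embryos into three freeze-damage
categories from VIS/NIR hyperspectral reflectance images. The central object
is the hypercube: an `H × W × B` array bound to a strictly increasing
wavelength axis in nm (default 477 bands uniformly spanning 400–1000 nm; the
original acquisition reports 477 wavelengths over that range without stating
the spacing, so the synthetic axis assumes uniformity). Spectra extracted
from cubes travel as a `SpectrumSet` — an `N × B` matrix plus per-row
metadata (seed id, category label 1/2/3, pixel coordinates, variety).

## Reflectance correction

Raw counts are converted to relative reflectance per pixel and band:

    R = (I0 − Ib) / (Iw − Ib)

with `Iw` a white-panel scan and `Ib` the dark-current frame. References may
be full frames or a single scan line broadcast along the motion axis, since
line-scan instruments commonly store line references. Positions with
`Iw ≤ Ib` are an error naming the offending bands, unless an epsilon floor is
configured. Negative corrected values (noise with raw < dark) are clipped to
0 and counted, keeping reflectance physically interpretable; values above 1
(specular pixels) are kept and logged. By construction the correction maps a
cube equal to white to exactly 1 and equal to dark to exactly 0 everywhere.

ENVI-style I/O (text header + flat little-endian binary, BIL/BIP/BSQ) is
implemented directly in `hypercube.py`; the write-then-read round trip is
bitwise exact for all three interleaves.

## Embryo segmentation

The embryo reflects more than the starchy endosperm near 500 nm, so a single
band suffices. The chain is: band image at the nearest band to 500 nm →
linear contrast stretch mapping the 1st..99th percentiles onto [0, 1]
("enhancement"; the simplest operation consistent with a stretch preceding
thresholding) → Otsu threshold → binary opening (disc radius 1) →
8-connected components → drop components below `min_area` (default 50 px) →
masks numbered 1..n in raster order of centroids.

Otsu is implemented as the 256-bin between-class-variance maximisation over
the image range. Empty histogram bins between the modes make the criterion
exactly flat over a run of candidate thresholds; the lowest threshold on the
plateau is returned, which makes the result independent of last-bit rounding
(an independent brute-force search and scikit-image's implementation agree
within this convention / within one bin respectively).

Foreground is taken directly as "brighter than threshold", i.e. a single
thresholding pass isolates the embryo; a two-stage whole-seed-then-embryo
split is out of scope. Touching seeds and orientation detection are likewise
out of scope (seeds are assumed placed embryo-up and non-touching).

## Pretreatment

Order is fixed: trim, then pretreat. Trimming keeps 1-based bands 31..460 of
a 477-band axis (430 bands), discarding the noisy spectrometer edges below
~444 nm and above ~985 nm.

* **SNV** — per spectrum, subtract the mean and divide by the standard
  deviation (n−1 denominator); invariant to positive affine distortions.
* **MSC** — per spectrum `x`, ordinary least squares `x ≈ a + b·ref`, output
  `(x − a)/b`. The reference is the calibration-set mean spectrum, computed
  once at fit time and stored with the pipeline so validation means and M2P
  pixel spectra are corrected against the identical reference.
* **5-3 smoothing** — the window-5, order-3 least-squares polynomial smoother
  (interior weights (−3, 12, 17, 12, −3)/35), iterated 2000 times by default.
  Edges use mirror padding, which is symmetric and preserves constants.
  One pass with fixed boundary handling is linear in the spectrum, so the
  iterated smoother is computed as a dense `B × B` operator raised to the
  iteration count by repeated squaring — O(log k) matrix products instead of
  k filter passes, which is what makes 2000 passes affordable on tens of
  thousands of pixel spectra. The operator path agrees with literally
  iterating `scipy.signal.savgol_filter` to ~1e−10 and preserves constants to
  ~1e−12 over 2000 passes. The same fitted pretreatment is applied to mean
  and pixel spectra alike: a coherent M2P prediction requires pixel spectra
  to pass through exactly the transform the model was trained on.

## Wavelength selection

All selectors operate on the trimmed 430-band axis; reports convert to nm and
1-based indices.

* **SPA** (successive projections algorithm). For every starting column, a
  chain grows by repeatedly adding the column whose component orthogonal to
  the span of the chain has maximum norm (columns are mean-centred for the
  projections; an exact duplicate of a chain member has zero residual and can
  never be selected). Every prefix of every chain with size in
  [n_min, n_max] = [3, 20] is scored by ten-fold cross-validated
  misclassification of a multiple-linear-regression discriminant on one-hot
  labels; the minimum score wins, ties broken by fewer variables then lower
  starting column. Chain construction is unsupervised, scoring supervised.
  Identical prefixes reached from different starts are scored once (cached).
* **PCA selection** — for each of the first 3 principal components, the 7
  columns of largest absolute loading; union, sorted. How a PCA is turned
  into a wavelength list is genuinely underdetermined; the loading-magnitude
  rule is an interpretation and is flagged as such.
* **X-loading** — a PLS model (5 latent variables by default) of the one-hot
  labels on the spectra; columns are ranked by the maximum over responses of
  the absolute regression coefficient, and the top 20 *local maxima* of that
  profile are kept (global top-k fills in if fewer peaks exist).
* **Full band** — all columns.

Default selection sizes (≤ 20 variables) match the convention that selection
reduces 430 inputs to "no more than 20".

## Classification

All three models store their full preprocessing provenance (trim rule, fitted
pretreater, band selection, feature scaler) so any new spectrum — a held-out
mean or a single pixel — is transformed exactly as calibration data were.
Hyperparameters are chosen by ten-fold stratified cross-validation with fold
assignment a pure function of (n, seed); reruns reproduce them exactly.
Folds are stratified by class (the plain convention would also work; we
stratify and document it).

* **PLS-DA** — one-hot labels, mean-centred X and Y, latent variables by the
  PLS recursion (scikit-learn's `PLSRegression`, no scaling); the component
  count (≤ 15) minimises CV misclassification, ties to fewer components.
  Prediction is the argmax of the three fitted responses. With the maximum
  feasible components on full-rank X the fitted values coincide with
  multivariate least squares, and a hand-coded NIPALS recursion is the
  independent oracle for the coefficients in the tests.
* **KNN** — Euclidean distance on columns standardised with calibration
  statistics; K from {1, 3, …, 15} by CV, ties to smaller K. Tie-breaking is
  part of the contract: equal distances resolve to the lower training-row
  index, equal vote counts to the class with the smaller mean distance among
  the tied classes (then the lower category). This is why KNN is implemented
  directly rather than via scikit-learn.
* **RBF-SVM** — one-vs-one `SVC` on standardised columns; (c, g) from the
  conventional grids c ∈ {2⁻⁵…2¹⁵}, g ∈ {2⁻¹⁵…2³} (powers of 4) by CV, ties
  to smaller c then smaller g.

Evaluation reports accuracy in percent and the 3 × 3 confusion matrix, and
flags the conventional 80% accuracy line used when comparing
pretreatment × selector × model cells.

## M2M / M2P visualisation and the decision rule

M2M (mean-to-mean): the classifier trained on calibration mean spectra
predicts each seed's mean spectrum; the embryo mask is filled with the
category colour. M2P (mean-to-pixel): the same classifier predicts every
embryo pixel, giving a class map and per-seed category fractions
p = (p₁, p₂, p₃). Embryo edges sit higher than the embryo centre and are
noisier, which is the motivation for deciding seeds by thresholded fractions
rather than by pixel majority alone.

The decision rule with per-variety thresholds t (hand-picked in the reference
tables: 0.37/0.32/0.44, 0.55/0.239/0.45, 0.38/0.385/0.34):

1. exceed set E = {c : p_c ≥ t_c} (≥ rather than >: no reference case sits
   exactly on a threshold, so either reading reproduces them);
2. |E| = 1 → that category;
3. |E| ≥ 2 → argmax over E of p_c ("the bigger fraction"), ties to the lower
   category;
4. |E| = 0 → argmin over all c of |p_c − t_c|, ties to the lower category.
   The absolute difference reproduces every printed subtraction in the
   reference tables even where p exceeds t in another column.

`search_thresholds` grid-searches thresholds maximising calibration agreement
— an extension beyond the hand-picked values, clearly marked as such.
The discrete class map is the default rendering (fixed 3-colour legend);
the continuous winning PLS-DA response per pixel is exposed as an optional
layer (`response_map`) without claiming it matches any particular published
rendering.

## Synthetic scenes and spectra

No raw images are deposited, so `synth` generates them. Spectral templates
are Gaussian-bump mixtures, not literature corn spectra: only the pipeline's
statistical behaviour is under test, not corn biochemistry.

* **Background** ~0.04–0.05 (dark stage); **endosperm** dark in the visible
  (~0.13 at 500 nm) and bright in the NIR (starch); **embryo** bright near
  500 nm (~0.5), which is what makes the single-band segmentation work.
* **Damage model.** Each seed carries a latent severity s with class means
  +sep, 0, −sep (sep = `separation`, default 1) and within-class spread
  `severity_sd` = 0.20. The embryo spectrum responds in two windows: a
  pigment bump at 575 nm, linear in s (amplitude 0.035), and a C–H-overtone
  bump at 900 nm with an accelerating (quadratic) term (amplitude 0.018,
  curvature 0.6). The curvature is essential, not decorative: if the three
  class means were collinear in band space, the middle class would be masked
  for any least-squares one-hot discriminant (its linear response can never
  win the argmax between its neighbours) — a well-known failure mode of
  regression-based discriminants. Gradual pigment loss with accelerating
  NIR changes under severe damage is also the physically sensible shape.
* **Scenes.** Seeds are non-touching ellipses on a grid (raster-ordered ids),
  endosperm radii (9, 7) px, embryo sub-ellipse (6, 4) px offset toward one
  end; per-pixel multiplicative gain (sd 0.02), per-pixel band noise
  (sd 0.02), and a ×3 noise multiplier on the one-pixel embryo edge ring.
  Raw counts are synthesised by inverting the black/white correction against
  per-line white (lamp spectrum × column vignette) and dark (offset + ripple)
  frames, so the correction step is exercised for real and recovers the
  encoded reflectance to float32 precision.
* **Desk-scale spectra.** `make_spectra` emits per-seed mean spectra directly:
  class template at the seed's severity, times a per-spectrum gain
  (sd 0.02), plus an offset (sd 0.005) and band noise (sd 0.008) — the
  gain/offset pair is the scatter-like distortion MSC/SNV exist to remove.
* **Study-design defaults.** 60/60/60 seeds per class (a 60/60/24 preset
  mirrors the smallest variety), 477 bands over 400–1000 nm, stratified 2:1
  calibration:validation split (180 → 120/60).
* Generation is a pure function of the `SceneSpec` including its RNG seed;
  identical specs give bitwise-identical output.

Noise and separation defaults were calibrated once so that the benchmark
pipeline (5-3 smoothing + SPA + PLS-DA) attains validation accuracy above 90%
with margin while remaining below saturation on desk-scale spectra (93–98%
across seeds; ~95–99% calibration). At `separation=0` the classes are
identical and accuracy is chance; accuracy is monotone in separation.

### What the generator does and does not emulate

It emulates the features the pipeline's correctness depends on: smooth
class-dependent reflectance differing mainly in 450–700 nm and 850–950 nm, a
segmentable bright embryo, scatter-like per-spectrum distortions, per-pixel
noise with elevated embryo-edge noise, per-line reference structure, and the
class-balance/split design. It does not emulate real corn biochemistry,
radiometric calibration error, touching or rotated seeds, within-embryo
spatial structure (scutellum vs. axis), detector nonlinearity, or wavelength
miscalibration. Passing tests therefore demonstrate that the pipeline
recovers known structure under realistic nuisance variation — not that any
particular accuracy would be attained on real seed images.

## Numerical choices and degenerate inputs

* Band-index reports are 1-based inclusive (matching "31 to 460"); all
  internal indexing is 0-based half-open.
* `nearest_band` ties resolve to the lower index.
* Otsu plateau ties resolve to the lowest threshold; constant images are an
  error (no threshold exists).
* SNV of a constant row, MSC with zero slope or a constant reference, SPA on
  a matrix too rank-deficient for `n_min` orthogonal steps, and empty
  hyperparameter grids are errors, not silent fallbacks.
* The SPA projection tolerance is 1e−10 relative to the largest column norm.
* Decision-rule ties (equal fractions or equal differences) resolve to the
  lower category; degenerate in practice.
* Fractions quoted at limited precision (e.g. 5 decimals) may not sum to 1
  exactly; `CategoryFractions` takes an explicit `atol` for such inputs while
  computed fractions keep the strict 1e−12 check.

## Problem sizes used in the shipped checks

The end-to-end benchmark runs the full default scene (180 seeds, 477 bands,
~320 × 288 px, ~14 000 embryo pixel spectra) — about half a minute on one
CPU. Unit and property tests use reduced scenes (9–30 seeds, 121 bands) and
small matrices chosen so every brute-force oracle remains exhaustive.

## Known limitations

* The exact wavelength lists a given instrument/selection run would produce
  are data-dependent and not reproducible without the original images; only
  structural properties (counts, window membership, oracle equivalence) are
  asserted.
* SPA scores chains with an internal ten-fold CV/MLR convention; other
  SPA variants score with different validators and may pick different sizes.
* The smoothing operator is dense (`B × B`); for axes beyond a few thousand
  bands a banded representation would be preferable.
* One published decision-table row is internally inconsistent with the
  stated minimum-difference rule; the implementation follows the rule (see
  the test data's note).
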