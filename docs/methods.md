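# Methods

## What the synthetic generator emulates

The generator stands in for a single-plant turntable imaging rig. Each scene
is a set of elliptical leaves arranged around a vertical stem axis inside a
square frame of configurable physical width (default 64 cm at 512×512 px,
256 px in the demo pipeline — geometry is resolution-independent because all
downstream measurements go through the plate calibration). A circular white
plate of 30 cm diameter sits in the frame and fixes the cm-per-pixel scale
exactly as a physical ruler plate would. Each plant is rendered as one top
view and six side views at 60° steps; the side projection maps a leaf at
azimuth φ viewed from angle α to horizontal offset `r·cos(φ − α)`.

Trait model and defaults:

* Leaf number: `LN ~ max(1, Poisson(μ(t)))` with logistic mean
  `μ(t) = 30 / (1 + e^{−0.15(t−40)})` (asymptote 30 leaves, inflection at
  day 40). The one-leaf floor keeps every mask nonempty; the exact mean is
  `μ + e^{−μ}`, which the Monte-Carlo tests use as their closed-form oracle.
* Total leaf area: logistic with L = 1500 cm², k = 0.12 /day, t₀ = 45,
  times mean-corrected lognormal noise (CV 0.10). Chosen so a mature plant
  has a realistic potted-soybean canopy (~40 cm tall, ~20 cm radius).
* Leaf fresh weight: allometric in area, `LFW = c·A^d` with c = 0.02,
  d = 1.05 and lognormal noise (CV 0.08) — no generative trait model is
  published, and a power law both matches how mass scales with area and
  makes the feature–trait relations power-law-like, which is the regime the
  published per-trait models (quadratic and `a·x^b`) describe.
* LAI: total leaf area divided by the floor (pot) area of a 25 cm pot
  (491 cm²). LAI is treated as an arbitrary positive scalar, not clamped to
  a physical 0–10 range, because the published per-trait tables use it on an
  area-like scale.

Masks are produced by an analytic pixel-centre-in-ellipse test rather than a
polygon scan-line. Two reasons: the inclusion test squares signed offsets,
so mirrored geometry rasterises to a bit-exact mirrored mask (the 0°/180°
side-view symmetry oracle relies on this, together with trigonometry that is
exact at multiples of 90°), and the per-leaf raster is the single shared
definition used both to build `plant_mask` and to verify the
mask-equals-union-of-leaves invariant bit-exactly. The stored `leaf_shapes`
polygons are 64-gon outlines kept for serialisation.

Rendering guarantees, by construction of the palette noise bounds, that
plant pixels satisfy `2G − R − B > 0` strictly and background/plate pixels
do not. The reference segmenter (excess green + Otsu + small-component
removal, min 16 px) is therefore near-perfect on rendered scenes; that is
intentional. What passing tests show is that the *pipeline machinery* is
correct under a segmenter that behaves like the published network did
(IOU ≈ 0.98); they do not show robustness to field conditions — occlusion
by neighbouring maize, specular soil, wilted (non-green) tissue and motion
blur are all absent from the generator.

## Segmentation evaluation

Standard confusion-matrix definitions are the default (IOU, pixel accuracy,
recall). The transcribed formulas that swap the FN/TN roles are available
behind `paper_literal=True` for auditing transcriptions; they are not used
anywhere else. Undefined ratios (empty denominators) are reported as NaN
with a warning, never silently as 0. Dataset-level scores are per-image
means. Grayscale is the exact rational mean `(R+G+B)/3` in float; the 8-bit
materialisation rounds half up so the conversion is bit-reproducible.

## Trait catalog

The 92-name default catalog splits 39 top / 53 side and, by category,
46 morphological / 12 colour / 34 texture (per view: top 16+6+17, side
30+6+17; the side view carries the height-dependent morphology). Decisions
worth recording:

* Convex hull is computed over the corners of occupied-pixel unit squares,
  not pixel centres, so one pixel has hull area 1 and the solidity
  `SC = PA1/CA1` is always ≤ 1 with no degenerate hulls. The 3-pixel
  L-shape therefore has CA1 = 3.5 px² and SC = 6/7 exactly.
* Perimeter is the crack-boundary length (count of pixel edges facing
  background), an exact integer that a brute-force loop can oracle.
* Fractional-height widths are measured bottom-up over a one-pixel band at
  `row = r_max − round(f·(H−1))`, because plants grow upward; `MW2_5` is
  the two-fifths-height width.
* Colour features per view: channel means, channel SDs, mean channel
  fractions, and the normalised differences `(G−R)/(G+R)`, `(G−B)/(G+B)`,
  `(R−B)/(R+B)` computed from channel means; the default catalog carries
  the means and normalised differences.
* Texture: grey levels are quantised into 32 fixed-width bins over [0, 256)
  (invariant to anything outside the mask); co-occurrence matrices at
  offset 1 px and angles 0/45/90/135° count only pairs with both pixels in
  the mask and are symmetrised. The catalog carries each GLCM statistic's
  mean and range over angles plus first-order statistics. Correlation of a
  zero-variance matrix is defined as 1. Single-pixel regions fail loudly
  (no pairs).
* Multi-view aggregation: side-prefixed features are the arithmetic mean of
  the six side views; top features come from the single top view.

Every registry entry records a one-line formula string, so replacing a trait
definition with an external catalog's is a data change.

## Predictor selection

Pearson ranking uses |r| with two-sided p-values from the t transform; no
multiple-testing correction is applied (none is part of the protocol), and
constant features rank last with NaN. Importance ranking is model-agnostic
permutation importance in the %IncMSE sense: out-of-fold MSE increase under
column permutation, averaged over repeats and folds, floored at zero and
rescaled to percentages summing to 100 (raw values retained, since flooring
discards sign information).

`choose_k_by_cv` scores the top-k predictor sets by cross-validated MAE on
common folds and by default applies the one-standard-error rule — the
smallest k within one SE of the curve minimum — which is the standard
defensible reading of "the error curve flattened"; `min` and `fixed:k`
rules are available. The error-curve estimator is pluggable and defaults to
ordinary least squares: the curve is evaluated up to 92 times per call, an
OLS curve is stable and cheap, and the selected set is consumed afterwards
by whichever final model the caller chooses.

## Regression

* ATPA rows with zero true value are excluded with a warning (the relative
  error is undefined); an all-zero target is an error. ATPA is unbounded
  below and capped at 100 only by perfection, not clipping.
* Model B (`y = a·x^b`) defaults to nonlinear least squares initialised
  from the log–log OLS line. Multiplicative vs additive error is not
  specified by the protocol, so the log–log estimator (exact under
  multiplicative lognormal error) is exposed as `fit_b="loglog"`.
* Random forest defaults: ntree = 300, mtry = max(1, p/3); `sweep_ntree`
  reports the cross-validated curve over 100–500 in steps of 50. The
  gradient-boosted family uses histogram GBT with learning rate 0.04,
  2000 iterations and squared-error loss; ordered boosting and categorical
  encodings are irrelevant here (all features are numeric).
* Cross-validation is a single seeded shuffle followed by a contiguous
  split (no stratification); the fold map depends only on (n, folds, seed),
  which is what makes the M1–M7 combination study a paired comparison.
  Folds with constant truth get NaN R² rather than a fabricated value.
* Outlier pruning reconstructs the Bonferroni outlier test on externally
  studentized residuals of a baseline linear model, removing the single
  most extreme significant row per iteration; it refuses to shrink the
  table below 10 rows.

## Growth curves

The standard 3-parameter logistic (no lower asymptote — traits start near
zero at the first vegetative stage). Initialisation: L₀ = 1.05·max(y), t₀
at the half-asymptote day, k₀ from a two-point logit slope between quantile
days; parameters are bounded positive for L and k. Identifiability needs
≥ 5 points straddling the inflection; flat series fail with a diagnostic.
Treatment comparison reports ΔL, Δk, Δt₀ with 200-resample residual-
bootstrap percentile intervals — an addition over a qualitative curve
comparison, labelled as such in the output.

## Pipeline and problem sizes

The global seed fans out into named per-stage substreams (SeedSequence), so
stages are independently reproducible and the whole manifest is
bit-identical across reruns. The demo configuration is 20 plants × 12
weekly sampling dates rendered at 256×256 — the package's desk-scale choice;
trait recovery is driven by counts and physically calibrated areas, not
pixel density. Simulation-based checks use 50 seeds × n=1000 for
coefficient recovery, 25 seeds for predictor-count selection and 100 seeds
for logistic recovery.

## Known limitations

* The renderer's separable colour classes make segmentation essentially
  perfect; segmentation-error propagation into traits is only exercised by
  swapping in external masks.
* Side views are 2-D projections without leaf occlusion modelling or
  perspective; top and side areas are therefore more consistent than in
  real canopies.
* The 92-trait registry matches the named main-protocol traits semantically
  (CA1/PA1/SC/MW…), but the long tail of catalog entries is this package's
  own documented set, not a symbol-for-symbol reproduction of an external
  supplementary file.
* Field-scale headline accuracies depend on the unreleased field data and
  are not reproducible here; the acceptance script reports the synthetic
  analogues computed at run time.
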