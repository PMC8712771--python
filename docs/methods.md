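# Methods

## The estimation problem

A rice panicle carries on the order of 50–150 grains, each either full
(filled; raised, center-bright appearance) or empty (unfilled; flat,
often with a dark crack along the middle). The seed setting rate is the
full fraction. Counting is done by an object detector on images taken in
a darkroom against black light-absorbing cloth, but at capture resolution
(4032×3024) the grains are too small relative to the frame for reliable
detection, so each image is cut into a 6×4 grid of 672×756 tiles and the
detector runs per tile.

Tiling introduces a bookkeeping problem: a grain lying across an interior
tile boundary appears as two truncated objects. The annotation scheme
makes this explicit with a third category, `half`, whose ground-truth
provenance is recorded as `H-full`/`H-empty`. After merging tile
detections back into image coordinates, the corrected estimator

    RSSR_a = (NF + PH·NH/2) / (NF + NE + NH/2)

treats `NH/2` as the number of cut grains (each interior cut yields
exactly two half boxes) and assigns each cut grain probability `PH` of
being full.

### The PH prior

Detectors report plain `half` without provenance, so `PH` must come from
elsewhere. The package uses a linear model on the full fraction among
whole grains in the same image, `PH = slope·Ratio1 + intercept` clamped
to [0, 1], with default coefficients `slope = 0.797`,
`intercept = 0.1972` (a published calibration with Pearson correlation
0.8327 between `Ratio1` and `Ratio2`, the full fraction among cut
grains). The intuition: whether a grain is cut by a tile boundary is
nearly independent of whether it is full, so `Ratio2 ≈ Ratio1`; the
linear form absorbs the residual coupling. `fit_ph_model` refits the line
by ordinary least squares, and `ks_consistency` (two-sample
Kolmogorov–Smirnov, asymptotic p-values) checks the distributional
consistency of the two ratio samples that justifies the linear pooling.

The error of the corrected estimator is exactly
`(PH − f_cut)·(NH/2)/(NF + NE + NH/2)` where `f_cut` is the true full
fraction among cut grains — zero when the prior is exact, and bounded by
the half fraction when it is not. This identity is asserted numerically
in the test suite.

## Coordinate and format conventions

Boxes are continuous, origin top-left, half-open
`[x_min, x_max) × [y_min, y_max)`; half-open intervals make the tile grid
a true partition (no pixel counted twice), which is what makes the
two-boxes-per-cut-grain premise exact. IOU is computed analytically on
rectangles; a pixel-rasterization oracle exists only in the tests.

VOC XML files (LabelImg dialect) store 1-based inclusive integer corners;
reading maps `xmin → xmin−1` (half-open), writing rounds fractional
corners to the pixel grid. The category vocabulary is closed: `full`,
`empty`, `half`, `H-full`, `H-empty`, case-insensitive.

## Tiling rules

* Grids that do not divide the image evenly put the remainder in the last
  row/column, keeping the partition exact.
* A grain part with area fraction `f` in a tile is: copied unchanged if
  `f = 1`; relabeled `half` (with provenance subtype) if
  `min_area_fraction ≤ f < 1`; dropped if smaller. The default
  `min_area_fraction = 0.15` reflects that tiny slivers are unlabelable
  in practice and would inflate `NH`; it is configurable, and 0 keeps
  every positive-area part.
* A grain cut by a grid corner yields 3–4 parts, which biases `NH/2`
  upward; the cutter warns when this happens rather than silently
  correcting, keeping the `NH/2` convention intact.

## Synthetic scenes

The generator emulates the darkroom capture statistics: near-black
background (gray level 12 with σ=1.5 sensor noise), 1–4 panicles per
image, grains strung along gently curving stems with per-panicle counts
drawn from a configured range, category Bernoulli(`true_rssr`) per grain.
Grains are rotated ellipses: full grains get a center-bright Gaussian
shading profile (base 110, peak +120), empty grains a flat body (150)
with a medial crack darkened by `crack_contrast` (default 60). A single
overhead light source is approximated by a 5% top-to-bottom brightness
ramp. Ground-truth boxes are the tight axis-aligned boxes of the
ellipses; truth counts are exact by construction, and identical
configurations give bit-identical images.

The default canvas is 1008×756 — a quarter-linear-scale version of the
capture geometry, so the standard 6×4 grid gives 168×189 tiles and the
tiling arithmetic matches the full-scale setup at desk-friendly cost.
Default `true_rssr = 0.85` and per-panicle counts of 40–80 sit in the
middle of the ranges observed on real panicles (rates roughly 0.65–0.95,
55–150 grains per panicle).

What the scenes do **not** model: awns, leaves and stem occlusion,
photoreal grain texture, specular highlights, inter-grain contact
(placement enforces a pairwise box-IOU cap, default 0.05), and the
full-to-empty appearance continuum of partially filled grains. Passing
tests therefore demonstrate the correctness of the bookkeeping and the
estimator, and that the classification cues are usable — not that the
baseline detector would survive field imagery.

## Baseline detector

A deliberately simple, deterministic, trained-model-free detector that
exercises the detector interface on synthetic tiles: Otsu global
threshold (floored at 35% of the tile maximum so dim stems stay out of
the foreground), 8-connected components within area bounds
(40–5000 px²), tight component boxes. Classification: a component
touching the tile border within 1 px is `half` (that is how halves arise
from tiling); otherwise the mean intensity of a 2.5 px disk at the
centroid is compared with the component mean — positive margin means
center-bright (`full`), negative means crack-dark (`empty`). The centroid
disk is sampled on the raw grayscale patch rather than on component
member pixels, because a crack dark enough to fall below the foreground
threshold is excluded from the component mask — exactly the evidence the
classifier needs. Confidence is the absolute margin scaled by 1/100 and
clamped to [0.5, 1].

## Evaluation conventions

* Matching is greedy, confidence-descending, one-to-one, at an IOU
  threshold (headline 0.5; 0.25/0.75 variants), the standard Pascal-VOC
  interpretation; unmatched truths are false negatives.
* AP is the raw precision–recall staircase sum with `recall(0) = 0` and
  no interpolation; all-point interpolation is available behind a flag.
  mAP is the unweighted class mean, excluding (with a warning) classes
  with no ground truth.
* RMSE is `sqrt(MSE)`. The agreement index `r_eq = 1 − SSres/SStot` is a
  coefficient-of-determination form, reported under its own name to avoid
  confusion with Pearson correlation.
* Count accuracy and rate accuracy are both the symmetric ratio
  `100·min/max` of the compared pair — the smaller value as a percentage
  of the larger. This form reproduces all 30 per-sample accuracy cells
  (and their column means 97.69 / 93.20 / 99.43) of the bundled
  10-panicle validation table; the asymmetric form
  `100·(1 − |m−a|/m)` does not (it misses three cells by 0.01–0.02).
* Undefined quantities (zero denominators) surface as NaN, never as
  silent zeros; F1 is defined as 0 when precision + recall = 0.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
quarter-scale canvases, 20-scene detector benchmarks, 500-pair prior
refits, and 1,000-trial geometry/AP property suites. These sizes keep the
statistical checks well-powered (the OLS standard error of the refit
slope at n=500 is ≈0.011, an order of magnitude below the asserted
tolerance) while the whole suite runs in seconds.

## Known limitations

* The bundled validation table carries the published algorithm rates
  verbatim because the half-grain counts behind them were not published;
  those cells are inputs, not recomputable outputs.
* `NH/2` is biased when corner cuts occur or when a sliver is dropped on
  one side of a boundary only (odd `NH`); the package warns on the former
  and accepts the latter as part of the estimator's design.
* The per-image prior ties `PH` to the same image's `Ratio1`; images with
  `NF + NE = 0` (all grains cut) have no defined `Ratio1` and yield NaN
  rates rather than a fallback estimate.
* The baseline detector's thresholds are tuned to the synthetic
  appearance model and make no claim of robustness to real imagery; real
  detectors should enter through the detection-table adapter.
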