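# Methods

This note records the model, the parameter choices that matter, what the
synthetic phantoms do and do not emulate, and the numerical conventions.
Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting and model

IBC rarely forms a discrete mass; mammographically it shows as diffuse skin
thickening and a unilateral rise in parenchymal density.  Both markers are
intrinsically *bilateral*: a bright skin band or dense parenchyma is only
diagnostic relative to the contralateral breast.  The system therefore
classifies right/left ratios, not absolute measurements, which also removes
most inter-machine and exposure variation.

The classifier is deliberately rule-based.  With cohorts of a dozen cases,
fitted models (SVMs, neural networks) cannot be validated; a Mamdani fuzzy
system encodes the radiological reading — "all three ratios clearly below
1", "all near 1", "all clearly above 1" — as three rules over
Low/Medium/High linguistic terms and exposes every parameter for
inspection.  Off-diagonal linguistic combinations (e.g. mean ratio Low but
density ratio High) are intentionally ruleless: they represent contradictory
evidence, and the system then returns the conservative fallback (non-IBC,
likelihood 0) and flags that no rule fired.

## Feature extraction

Per breast, after artifact removal and segmentation:

* **Nipple and quadrants.**  The nipple is the arc point farthest from the
  chest wall (ties to the lowest row).  The halving line through it is
  perpendicular to the chest wall (CC) or to the breast's principal axis
  (MLO); the inferior half (larger mean row) is the analysis ROI, matching
  the early-IBC predilection for the inferior breast.
* **Skin band.**  Quadrant pixels within `w` pixels of the breast arc,
  where the arc pixel layer itself is depth 1 (so the band is
  distance-to-arc ≤ w−1).  Arc pixels within 2 px of the chest-wall
  junction are dropped, and pixels nearer the chest wall than the arc are
  excluded.  Default `w` = 2 % of the breast minor-axis length, floored at
  3 px: scale-invariant and non-degenerate at phantom resolution.  A width
  at or beyond the minor axis saturates the band to the whole ROI (logged).
* **Moments.**  Intensities are quantized to z = round(255·I); μ and σ are
  the pmf mean and SD divided by 255, so they live on the same [0, 1] scale
  as the bundled cohort's printed values.  The tests pin them to plain
  sample statistics at 1e−12.
* **Density.**  γ is the fraction of supra-Otsu pixels in the quadrant,
  with the skin band *plus a 2 px margin* excluded first — otherwise the
  bright band itself inflates the "dense" fraction.  Otsu is computed
  per breast on the quadrant histogram (256 levels, between-class variance,
  ties to the lowest maximizer).  Note the tie convention: on an exactly
  balanced two-level histogram every threshold between the modes is a
  maximizer and the *lowest* (the low mode's level) is returned; since
  binarization uses `z > z*`, this still separates the modes.
* **Ratios.**  Always right/left, regardless of the diseased side.  Both
  σ values are floored at 1/255 (one quantization step) before the ratio so
  a constant band yields f2 = 1 rather than 0/0.

Feature statistics are computed on the raw normalized intensities, not on
contrast- or decorrelation-stretched images: the stretches are per-image
affine maps, so stretched means of the two sides are not commensurable and
their ratio is meaningless.  The stretches remain available in
`ibccad.preprocess` (and the CLI) for display and for contrast-sensitive
downstream use.

### Preprocessing conventions

* Foreground threshold: the *lowest* threshold of a three-class multi-Otsu.
  A mammogram histogram has three populations (background, fatty, dense);
  a two-class Otsu can land between the tissue modes and cut fatty tissue
  out of the breast.  Images with too few distinct levels fall back to
  two-class Otsu.
* Polarity: if thresholded foreground dominates the image border, the image
  is white-background and is inverted (mammograms are bright-on-dark).
* Artifact removal keeps only the largest connected foreground component,
  preserved pixel-for-pixel; annotation text blocks vanish.
* View detection: MLO iff a chest-wall corner triangle (leg = 25 % of image
  height) has foreground occupancy ≥ 0.6 (ties deliberately go to MLO);
  both chest-wall corners are checked and the larger occupancy is the
  confidence.
* Decorrelation stretch on a single-channel image is classically
  under-defined, so a 3-channel stack (intensity, Gaussian-smoothed
  intensity, gradient magnitude) is decorrelated: covariance whitened,
  component variances equalized to the largest channel variance, transform
  inverted, intensity channel rescaled by its 0.5/99.5 percentiles and
  clipped.  Percentile (not min–max) rescaling stops gradient outliers from
  compressing the bulk contrast.  The enhancement guarantee — variance not
  decreased, band-vs-interior gap strictly widened — holds on the breast
  region and is tested there; *frame-wide* variance can legitimately drop
  because the background/tissue split is not the contrast being enhanced.
* Coordinates are (row, column), 0-based, origin top-left; masks are
  boolean pixel sets.

## Fuzzy classifiers

Shipped Type-1 trapezoids, shared by all three features (breakpoints
a ≤ b ≤ c ≤ d; infinite values are open shoulders):

| term | a | b | c | d |
|------|------|------|------|------|
| L | −∞ | −∞ | 0.55 | 0.90 |
| M | 0.75 | 0.90 | 1.20 | 1.55 |
| H | 1.05 | 1.55 | +∞ | +∞ |

These place the Medium core symmetrically around 1.0 (the non-IBC locus)
with crossovers near ±20 %, and are validated by the test suite against the
bundled cohort's published confusion counts.  Rule strength is the min
t-norm; defuzzification is the strength-weighted average of the singleton
consequents (height defuzzification); decision is `likelihood > 0.5`, so a
tie at exactly 0.5 reads non-IBC.  The no-rule-fired fallback is 0.0
(non-IBC): conservative, and consistent with the 100 % precision the
shipped defaults achieve on the cohort.

The interval Type-2 system widens each feature's trapezoids by a per-feature
FoU width δ: upper bound breakpoints shifted outward by δ, lower bound
inward (a collapsing core pinches to its midpoint).  δ = 0 reproduces the
Type-1 term exactly, which yields the collapse property tested at 1e−12:
zero-FoU Type-2 likelihoods equal Type-1 likelihoods for any input and rule
base.  Rules fire as intervals (min of lower degrees, min of upper
degrees); type reduction is the Karnik–Mendel iteration over the singleton
consequents, returning the exact interval [y_l, y_r] of achievable weighted
averages (verified against an exhaustive endpoint-assignment oracle — valid
because a linear-fractional objective over a box attains its extrema at
vertices); the crisp likelihood is the interval midpoint.

The FoU widths are not hand-picked: `calibrate_fou` walks a deterministic
grid (0 to 0.5 in 0.05 steps per feature, ordered by total width then
lexicographically) and returns the first configuration classifying the
whole reference cohort correctly.  On the shipped cohort that is
δ = (0.25, 0.05, 0.0) for (f1, f2, f3): the single Type-1 miss has a mean
ratio (0.83) between the Low and Medium supports, so f1 needs the widest
uncertainty band.  Calibrating on the same 14 cases that are then reported
is a transparent in-sample fit — with n = 14 there is no held-out set, and
the result should be read as "a uniform-FoU Type-2 system consistent with
the published per-case features and 100 % accuracy exists", not as an
out-of-sample performance claim.

## Evaluation

IBC is the positive class.  Accuracy, recall, precision and F1 follow the
standard confusion-matrix formulas, in percent with two decimals; zero
denominators report as undefined (`None`), never 0.  ROC is a threshold
sweep over the unique scores with trapezoid AUC, which equals the
Mann–Whitney pair statistic with half-credit ties (tested to 1e−9 and
against scikit-learn).  The cohort report also prints the Type-1 accuracy
on an (n−1)-case denominator because the published accuracy/AUC pair for
that classifier is arithmetically consistent only with 13 cases (12/13 =
92.31 %) although the cohort has 14 (13/14 = 92.86 %); both readings are
surfaced rather than silently choosing one.  The Type-1 continuous-score
AUC is reported but is not a reproduction target: with the shipped
piecewise-linear memberships most negatives defuzzify to exactly 0, and the
resulting tie structure (AUC 91.67 % here) depends on score calibration
details that the published material does not constrain.

## The phantom generator

Phantoms exist to make every pipeline stage testable offline with known
ground truth; they are geometric stand-ins, not realistic mammograms.

One breast = a half-ellipse against the chest-wall image edge (CC), plus a
triangular pectoral wedge in the chest-wall corner (MLO), with a skin band
of stated thickness along the curved arc, a nipple bump at the apex, a
bimodal interior (fatty mode 0.30, dense mode 0.75) realizing a stated
dense fraction exactly (round(f·N) pixels via a seeded permutation), and
optional annotation blocks plus clipped additive Gaussian noise.  The right
image has its chest wall on the left edge; the left image is mirrored.
Default geometry: 256×256 px, half-axes ≈ (100, 105), band 4 px at
intensity 0.65.

Choices worth noting:

* **Band texture.**  Bands carry a seeded Gaussian intensity texture with a
  parameterized SD (default 0.05); a constant band would make the σ feature
  0/0 on every phantom.  The truth σ-ratio is the ratio of the SD
  parameters, floored at 1/255 per side like the extractor.
* **Shared interior stream.**  The dense-pixel placement stream is shared
  between the sides (band texture and noise streams stay independent), so
  equal-parameter sides realize mirrored interiors and a symmetric phantom
  is actually symmetric; otherwise binomial subsampling of dense pixels
  into the lower quadrant adds ±2–4 % noise to the density ratio of even a
  "symmetric" case.
* **IBC series pattern.**  `make_case_series` elevates one random side's
  band intensity (×1.4, capped at 0.85 so intensity + 2 SD stays below 1.0
  and clipping cannot bias the realized moments), band thickness (+2 px),
  band SD (×1.4) and dense fraction (+0.25); non-IBC cases get ±3–5 %
  right/left jitter.  Series noise SD is 0.01.

What phantoms do *not* emulate: real parenchymal texture, masses and
calcifications, pectoral-muscle gradients, compression and exposure
variation, or positioning differences between views.  Passing the phantom
recovery tests (median relative feature error < 10 % over 20 seeded cases)
shows the measurement chain is unbiased on images satisfying its geometric
assumptions — not that the features are accurate on clinical data.  The
classifier benchmarks, by contrast, run on the published per-case clinical
feature values, which are bundled verbatim and authoritative.

## Numerical conventions and degenerate inputs

* All randomness flows through explicitly seeded `numpy` generators;
  repeated runs are bit-identical.
* Quantization is `round(255·I)` everywhere (pmf, Otsu, density), so the
  extractor and the moment oracles share one grid.
* Karnik–Mendel: consequents sorted ascending (stable), endpoints iterated
  to fixed point (≤100 iterations, exact-equality stop); a zero denominator
  during iteration falls back to an exact switch-point scan.  If even the
  upper firing strengths sum below the firing floor (1e−9), the reduced
  interval is [0, 0] flagged "no rule fired".
* Blank/constant images raise immediately; a mask touching three or more
  image edges raises an ambiguous-orientation error; a degenerate arc
  (< 10 points) and an empty quadrant or band raise with the offending
  stage named, annotated with the breast side.

## Known limitations

* The cohort is 14 cases; every performance number in this package is an
  in-sample description of those cases, and the Type-2 FoU is calibrated on
  them (see above).
* Membership breakpoints are a reconstruction constrained by the published
  per-case features and confusion counts, not the original system's
  parameters; they are config-overridable (`ibccad.config`).
* Skin-band width is measured in pixels, not millimeters; DICOM pixel
  spacing is read but not used for calibrated measurements.
* MLO phantoms approximate the pectoral muscle as a uniform wedge; the
  principal-axis nipple-line construction is untested against clinical MLO
  positioning variability.
* Granulomatous mastitis and cellulitis — the main radiological mimics of
  IBC — are outside both the cohort and the phantom family; the classifiers
  have never seen them.
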