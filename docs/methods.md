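# Methods

## Problem and scope

`osteofract` implements a radiomics pipeline for pre-treatment MR images of
bone tumors: monofractal shape/texture features and co-occurrence texture
features are extracted from cropped grayscale regions of interest (ROIs),
and their ability to predict a binary chemotherapy-response label (good =
necrosis > 90% at surgery, poor otherwise) is evaluated with
optimal-cutpoint categorization, stepwise logistic regression, and
bootstrap bias-corrected ROC analysis. Because clinical images of this kind
cannot be redistributed, the package ships a synthetic phantom and cohort
generator that reproduces the *structure* of such a study (22 patients,
3 imaging planes x 2 images each, a small SFR group difference) so the full
pipeline can be exercised and validated end to end.

## Image processing chain

An ROI is an 8-bit grayscale array with an optional boolean tumor mask
(radiologist-drawn border in the clinical setting; star-convex synthetic
mask in phantoms). The chain produces four binary variants:

1. **binarized** — foreground = intensity strictly above a threshold.
   Default threshold: Otsu's between-class-variance maximizer; a fixed
   threshold is available for constant or deliberately controlled images.
   The chosen threshold is recorded in the provenance of every product.
2. **filled** — binarized foreground OR the tumor mask (the tumor area
   flood-filled with foreground).
3. **inverted_filled** — the complement of the filled frame, whole-frame.
4. **outline** — binarized foreground pixels with at least one background
   8-neighbor; out-of-frame neighbors count as background, so
   border-touching regions contribute their rim.

Conventions: row-major (y, x) storage, 0-based half-open crop rectangles,
8-connectivity for outlines. These are choices, not forced by the science;
they are fixed and documented so results are reproducible.

## Fractal features

**Box dimension.** A top-left-anchored square grid of side `r` covers the
frame (partial edge cells count); `N(r)` is the number of cells containing
foreground. For self-similar patterns `N(r) = const * r^-D`; `D` is the
magnitude of the OLS slope of `log N` on `log r` (natural logs; the slope
is base-invariant). The default size schedule is powers of two from 2 to
half the shorter side, requiring at least 4 sizes; analytic fixtures use
their natural scales (powers of 3 for the Sierpinski carpet, powers of 4
for the quadric Koch island) where the points are exactly collinear. No
grid-offset averaging is performed: a single anchored grid matches the
plain box-count definition and keeps exact fixtures exact.

Two variants are reported per image: `D_bin` (binarized image) and `D_out`
(outline image).

**Finite-size caveat.** For smooth curves (circle outlines), box sizes
approaching the curvature radius saturate the counts and bias the slope
upward; validation fixtures therefore keep `r` well below the object
scale. This is inherent to box counting at desk-size frames, not an
implementation artifact.

**Lacunarity.** Allain–Cloitre gliding box: an `r x r` window slides with
stride 1; with window mass `M`, `Lambda(r) = var(M)/mean(M)^2 + 1`
(population variance). The summary is the arithmetic mean of `Lambda(r)`
over the same size schedule (restricted to `r` strictly below the frame).
Homogeneous patterns give exactly 1; clustered patterns score higher.

**Space-filling ratio (SFR).** `SFR = D_filled / D_inverted`, the box
dimension of the tumor-filled frame over that of its whole-frame
complement. Both terms suffer the same finite-size effects of the frame,
so their ratio is comparable across ROIs with very different
tumor-to-background proportions — the motivation for the feature. SFR
requires a mask; without one, or when the mask covers the whole frame
(empty complement), SFR is recorded as missing with the reason, and the
remaining features are still produced.

## GLCM texture features

The co-occurrence matrix `P(i, j | dx, dy)` is the normalized histogram of
gray-level pairs at displacement `(dx, dy)`. Defaults: native 8-bit depth
(G = 256, uniform re-binning available), distance-1 displacements at
0/45/90/135 degrees, symmetric counting, and features averaged over the
four displacements — the common Haralick convention. When a mask is
present, only pairs with both pixels inside it count, keeping the texture
tumor-specific.

Five features: angular second moment (sum of squared probabilities),
inverse difference moment (`sum P/(1+(i-j)^2)`), contrast
(`sum n^2 * P_{|i-j|=n}`, identical to `sum P (i-j)^2`), correlation
(marginal-standardized covariance of the joint distribution; undefined and
reported as NaN on constant images), and entropy (base 2 by default;
`0 log 0 = 0`). Correlation is averaged over the displacements where it is
defined.

## Predictive evaluation

The positive class is **poor responder** throughout, and the AUC
orientation is never flipped: AUC is the Mann–Whitney probability that a
poor responder's value exceeds a good responder's (ties 1/2), so values
below 0.5 indicate a feature running higher in good responders and are
reported as-is.

Per-image rows are averaged to plane means, and the three plane means to a
per-patient average; a missing plane propagates missingness to the average
rather than silently reweighting. For every feature x section cell the
pipeline reports:

* **P-value** — a univariable logistic fit (Wald test) on values
  dichotomized at the optimal cutpoint: the midpoint between consecutive
  sorted distinct values maximizing the Pearson chi-square of the induced
  2x2 table (ties broken toward the more balanced split, then the smaller
  cut). Under perfect separation the Wald statistic is undefined and the
  cutpoint's chi-square p is reported instead (flagged in `p_method`).
* **AUC with bootstrap bias-corrected 95% CI** — stratified resampling
  within each class (so every replicate retains both classes); raw CI =
  percentile interval of the bootstrap AUCs; bias = mean bootstrap AUC
  minus observed; corrected CI = raw interval shifted by −bias, clipped to
  [0, 1]. Deterministic under a fixed seed.
* **Accuracy** — percentage of patients whose categorized prediction
  matches the label, at the optimal cutpoint, on the data the cutpoint was
  selected on.

The multivariable model is a forward-selection (entry P < 0.10, judged on
the Wald p of the candidate in the growing model) / backward-elimination
(stay P < 0.05) logistic regression over the categorized averaged
features, with a collinearity guard (perfectly correlated candidates are
skipped) and cycle detection (a recurring model state stops the loop). An
empty final model is a valid, flagged outcome. Spearman rank correlations
(mid-ranks for ties) of each feature against tumor volume and surface
complete the report. No multiple-testing adjustment is applied by default
— the full p matrix is emitted so users can adjust.

### Known statistical caveats, measured rather than hidden

Optimal-cutpoint ("minimum p") categorization inflates apparent
significance. Measured on this implementation with 12/10 null cohorts over
1000 seeds: the cutpoint chi-square p is below 0.05 in ~44% of null runs;
the reported Wald-on-categorized p — partially offset by the Wald test's
small-sample conservatism — in ~16%. The accuracy reported at the optimal
cutpoint is likewise training-set-optimistic, and because the cut
maximizes association (chi-square), not accuracy, it can even fall below
the majority-class rate on imbalanced data. These properties are asserted
and quantified in the test suite; users comparing features should lean on
the bootstrap-corrected AUC CIs and treat the univariable p-values as
screening quantities.

## Synthetic data

**Known-dimension fixtures** validate the estimators: filled square
(D = 2), 1-px line (D = 1), Sierpinski carpet (log 8/log 3), Sierpinski
triangle (log 3/log 2), a quadric Koch island boundary (log 8/log 4 = 1.5;
its rasterization is lattice-aligned so grid anchoring stays commensurate
with the construction), and seeded random dust.

**Tumor phantoms.** The background texture is a fractional-Brownian-style
field synthesized spectrally (amplitude ~ f^-(H+1), random phases,
H in (0,1); smaller H = rougher). The tumor mask is star-convex: a radial
harmonic profile scaled so the enclosed area matches a configured fraction
of the frame (measured area within 5% of target). An intensity offset is
added inside the mask. All generators are pure functions of their
configuration including the seed.

Direction of the roughness effect: with the threshold held fixed
mid-range (so foreground density is constant), rougher fields fragment
into finer granules that occupy more small boxes, and the measured
`D_bin` decreases monotonically in H — frozen as a regression test over
20 seeds. Under Otsu the threshold itself moves with the field's
histogram and can reverse this relation; the regression test therefore
pins the threshold.

**Cohorts, two tiers.** The *feature tier* draws per-patient feature
values from configured group normals (defaults: SFR 0.91 ± 0.02 good vs
0.94 ± 0.01 poor; all other features identically distributed in both
groups) and adds within-patient replicate noise (SD = 0.3 x group SD per
image); it feeds the statistics layer directly. The *image tier* writes
actual phantom PNGs: a per-patient target SFR is drawn from the group
distribution and converted to a mask-area fraction through a cached
calibration curve (coarse grid of area fractions, 3 probe seeds each,
linear interpolation; an unreachable target raises an error listing the
achievable range). The image-tier cohort uses a high tumor/background
contrast (140 of 255): below roughly 130 enough background speckle
survives binarization to pin the filled dimension near 2, making the SFR
range too narrow and non-monotone in the mask fraction; with speckle
suppressed the calibration is monotone over area fractions 0.06–0.55 and
spans SFR ≈ 0.66–0.97.

What the phantoms do *not* emulate: MRI physics (bias fields, partial
volume, coil inhomogeneity), anatomical context, inter-plane correlation
of real tumors, or radiologist variability in border drawing. Passing
tests on phantoms therefore demonstrates correctness and calibration of
the computational pipeline, not clinical validity of the features.

## Problem sizes and numerical choices

Validation simulations use deliberately modest sizes chosen to estimate
each property with adequate precision: 500 simulated cohorts x 300
bootstrap replicates for CI coverage (n = 20/20 per group, true AUC 0.8);
100 seeds for stepwise retention (n = 200, effect 1 SD) and for cohort AUC
recovery (n = 12/10, the study's group sizes); 200 seeds for the
permuted-label null; phantom frames of 128 px (64 px in smoke tests).
Tolerances on analytic dimensions reflect finite-size effects: ±0.02 for
the plane-filling square, ±0.05–0.07 for the recursive fixtures, ±0.1 for
the level-3 Koch boundary. Oracle-equivalence checks are at 1e-12;
exact-collinear fits at 1e-9. Degenerate inputs (constant images under
Otsu, masks covering the frame, single-class cohorts, zero rank variance)
raise typed errors or produce flagged missing values — never silent NaNs.

## Known limitations

* The clinical study this mirrors is not reproducible from data (its
  images are not public); all quantitative claims here are about synthetic
  cohorts with the reported effect structure.
* Box dimensions at 128-px frames carry finite-size bias; comparisons are
  meaningful within a fixed frame/schedule configuration, which the
  provenance columns record.
* The bias-corrected bootstrap implemented is the shifted-percentile
  variant; BCa is not implemented, but the `RocSummary` records bias and
  raw CI so alternatives can be layered on.
* Stepwise selection with cutpoint-categorized candidates inherits the
  optimism documented above; its output is a screening model, not a
  validated clinical predictor.
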