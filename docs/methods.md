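# Methods

## Morphometry

A nucleus is a closed polygon in 0-based pixel-center coordinates
(x rightward, y downward), implicitly closed, non-self-intersecting, with
nonzero area; point-in-polygon tests are boundary-inclusive. Geometric
features come from the polygon alone:

* **Area / perimeter** — shoelace area and Euclidean edge sum (via shapely).
* **Calipers** — projection widths of the vertex set on 180 directions over
  [0, π) (1° Feret resolution); max, min and mean over the grid. The maximum
  is additionally lower-bounded by the exact maximum pairwise vertex
  distance, which *is* the maximum Feret diameter, so `max_caliper` is exact
  while min/mean carry the grid's ~4×10⁻⁵ relative discretization.
* **Radii** — distances from the area centroid to the boundary resampled at
  1024 equal arc-length points; a centroid outside the polygon (pathological
  non-convexity) is flagged but still measured.
* **Moment ellipse** — axes of the ellipse with the polygon interior's exact
  second-order area moments (Green's-theorem vertex formulas); `major_axis`
  = 4√λ₁ so a true ellipse recovers its own axes.
* **Roundness** — 4πA/P², 1 for a circle; never exceeds 1 + ε for any simple
  polygon (isoperimetric inequality).
* **Fractal dimension** — box counting on the rasterized outline. The
  outline is rescaled so its longest extent spans 1024 grid cells, traced at
  ~0.3-cell steps, and occupied-box counts at dyadic sizes 8…256 are fit by
  least squares in log–log space; the negated slope is clamped to [1, 2].
  The normalization makes the estimate independent of absolute nucleus size,
  and the size window [grid/128, grid/4] covers the scales at which an
  outline's self-similar structure is actually resolved: a fourth-iteration
  Koch boundary measures within 0.01 of log 4/log 3 while smooth outlines
  measure ≈ 1.0–1.05.

Densitometric features use optical density OD = −log₁₀((L+1)/(I₀+1)) per
masked pixel, with L the BT.601 luminance (0.299 R + 0.587 G + 0.114 B) and
I₀ = 255 by default or the mean blank-field luminance when one is supplied.
Luminance is used because no single stain channel is canonical for
Papanicolaou-type stains; the incident level is configurable. Flat-field
correction multiplies each channel by mean(blank)/blank per pixel (blank
zeros treated as 1), clipped to [0, 255].

Three descriptors have no universally fixed formula; the package adopts and
documents these reference definitions:

* **Margination** — fraction of the integrated OD carried by the peripheral
  band of mask pixels within 0.1·r_eq of the boundary, where r_eq = √(A/π)
  is the equivalent-circle radius (for a uniform disc of radius 20 px the
  2-px band holds ≈ 1 − (18/20)² = 19% of the IOD). Defined as 0 when
  IOD = 0.
* **Heterogeneity** — fraction of mask pixels with |OD − mean| > SD (SD with
  population denominator N, a descriptor of the pixel set rather than a
  sample estimate). Defined as 0 when SD = 0.
* **Fractal dimension** — as above.

Colloid structures are measured identically to nuclei: any delineated
polygon yields a feature vector.

## RBF nucleus classifier

Classical three-layer construction: z-scored features (constant columns
dropped), k Gaussian hidden units with centers from k-means (10 restarts,
seeded), widths σⱼ = mean distance from each center to its 2 nearest other
centers (for k = 1, the mean point-to-center distance), and output weights by
ridge least squares of the design [1, Φ] against 0/1 targets (λ = 10⁻⁶,
escalated tenfold up to 3 times if the normal equations are singular). The
hidden-layer size is selected from the grid {10, 20, 40, 80} by balanced
accuracy on an internal stratified 80/20 holdout, then the winner is refit
on all training rows. A score ≥ 0.5 calls the nucleus malignant; ties go to
malignant deliberately (favoring sensitivity in a cancer screen).

Training rows are first sorted into a canonical (label, lexicographic
features) order so that every downstream float reduction — standardizer
means, k-means, the holdout draw — is invariant to the order the caller
stored the rows in; identical data and seed give bit-identical models.

Nucleus-level supervision is the case's histological diagnosis propagated to
its structures, the only labeling available in practice. A malignant slide
therefore contains genuinely benign-looking cells carrying a malignant
label, which bounds achievable nucleus-level sensitivity — the reason the
case-level aggregation stage exists.

## Case classifiers and threshold choice

A patient is called benign iff their benign-classified structure count
(numeric) or percentage (percent) **strictly exceeds** the threshold.
Candidate thresholds are swept over 1…100 (step 1) or 1.0…100.0% (step 0.1,
grid values rounded to one decimal); each candidate is scored on training
cases by case-level sensitivity and specificity (malignant positive), and
the candidate minimizing |sens − spec| wins, ties broken by higher overall
accuracy and then by the smaller threshold (deterministic, and marginally
favoring malignant calls). Along the sweep, sensitivity is non-decreasing
and specificity non-increasing by construction; the full sweep record is
retained in the threshold artifact. For ROC analysis the case score is the
negated benign statistic, so larger means more malignant.

## Metrics

All indices are ratios of raw confusion-matrix counts. This matters at the
second decimal: computing the positive likelihood ratio of the reference
percent classifier from rounded percentages gives 21.06, whereas the exact
counts give 21.04. Display rounding is half-up to 2 decimals; internal
values are full precision. Degenerate denominators yield NaN (proportions)
or +∞ (ratios) with a warning rather than an exception.

The two-proportion z-test uses the unpooled standard error for the 95% CI
(±1.96·SE) and the pooled standard error for z and the two-sided p. The
sample sizes entering the standard errors can be overridden independently of
the proportion denominators (`se_n1`/`se_n2`); this reproduces report styles
that normalize the variance by the whole study size rather than the
class-specific denominator, and both variants are exercised in the tests.

ROC curves sweep unique score values with ties grouped (scikit-learn) and
AUC is trapezoidal, equal to Mann–Whitney concordance with ties counted ½.
AUC variance, 95% CIs (clipped to [0, 100]) and the paired two-classifier
comparison use DeLong's midrank estimator, implemented here. Train-vs-test
AUC comparisons involve disjoint case sets and therefore use the unpaired
z = Δ/√(v₁+v₂) on the two DeLong variances.

## Synthetic cohort generator

The generator emulates only the *structure* of the validation cohort, not
thyroid cytology itself. Defaults: 447 cases, 64.4% benign; structures per
case negative-binomial with mean 92 and dispersion r = 10 (SD ≈ 31 — a
realistic spread for a manual selection of roughly a hundred nuclei per
slide), floored at 1, giving ≈ 41k structures. Within a case, each
structure's latent class follows the case label except for a contamination
fraction: 1% malignant-looking structures in benign cases and 20%
benign-looking structures in malignant cases (malignant slides carry many
normal follicular cells, histiocytes and colloid fragments). Features are
drawn from class-conditional multivariate normals on a standardized scale —
mean shift of 1.5 SD on area, IOD and OD-SD, 0.5 SD on the remaining 20
features, correlation 0.3 among the nine size features — then mapped
affinely to plausible native units and clipped to validity (positivity,
ratios ≥ 1, fractions in [0, 1]). Benign subtype labels (goiter, Hashimoto
thyroiditis, …) are decorative metadata and do not affect generation.

What passing tests on this cohort do show: the pipeline recovers planted
class structure through the full morphometry-free path (fit → predict →
tally → threshold → evaluate), its thresholding is monotone and
reproducible, and with the class signal removed the nucleus-level balanced
accuracy sits at exactly chance (no leakage through the case-level
plumbing). What they do not show: performance on real stained slides, where
feature distributions are non-Gaussian, correlated with slide preparation,
and not independent across nuclei of one patient.

The image renderer draws analytic ellipses (uniform, two-tone, or noisy OD
against a white background) with a 256-gon boundary on the true ellipse, so
morphometry can be checked against closed forms: area πab, Ramanujan
perimeter, axes 2a/2b, and the requested OD level (quantized to 8-bit
intensity, within 0.02 OD).

## Numerical and design notes

* Feature-vector ordering invariants (min ≤ mean ≤ max etc.) are enforced on
  construction with a 10⁻⁹ tolerance, since float reductions over a uniform
  pixel set can cross an exact bound by one ulp.
* The numeric case classifier uses an absolute count although cases differ
  in structure count; it is kept as a first-class variant because it is part
  of the system being modeled, with the percent classifier as the normalized
  alternative.
* The reference case thresholds (37 nuclei, 51%) bundled in
  `cytodx.reference` derive from the original, undistributed training data;
  they are documentation constants, not quantities the package can
  re-derive.
* Problem sizes in the test suite (a 60-case smoke cohort for pipeline/CLI
  contracts; the full 447-case default cohort for the recovery checks; 5,000
  z-test replicates; 1,000 caliper oracle polygons) were chosen to exercise
  each property at meaningful scale while keeping the suite fast to run.
* Known limitations: no automated segmentation (boundaries are inputs), no
  stain-specific spectral unmixing, no multi-class Bethesda prediction, and
  the RBF recipe (k-means centers, neighbor widths, ridge output) is one
  classical choice among several — hyperparameters are exposed in
  `RBFConfig` for sensitivity analysis.
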