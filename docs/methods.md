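# Methods

`muscletex` quantifies the *pattern* of muscle fat infiltration, not just
its amount. The input is a proton density fat fraction (PDFF) map — a
quantitative MR image whose voxel values are the percentage of MR-visible
protons attributable to fat — together with a binary region of interest
(ROI) over one muscle compartment. The output is a 12-number feature vector
per muscle (mean PDFF, 3 histogram features, 8 co-occurrence features) and
a statistical layer relating those features to isometric muscle strength.

## Feature model

### Preprocessing

Feature extraction assumes an isotropic grid, so that the 26-neighborhood
used by the co-occurrence analysis steps the same physical distance along
every axis. Maps are resampled trilinearly and masks by nearest neighbor
(re-binarized at 0.5) to 2.0 mm isotropic by default — the in-plane pitch
of a typical thigh CSE-MRI acquisition (native spacing 3.2 × 2.0 × 4.0 mm).
Resampling is center-aligned: output voxel center `(j + 0.5)·t` maps to
input coordinate `(j + 0.5)·t/s − 0.5`, which makes resampling at the
native spacing an exact identity.

Gray-level quantization maps in-ROI values to integers 1..Ng with
Ng = 200 equal-width bins:

    level(v) = ceil(Ng · (v − lo) / (hi − lo)),   level(lo) = 1.

By default the window `[lo, hi]` is the in-ROI min/max (per muscle), which
prevents sparse co-occurrence matrices at the low, narrow PDFF ranges of
healthy muscle; a fixed physical window `[0, 100]` % is available via
`quantizer.window: fixed` for sensitivity analysis. Quantization happens
after resampling. A constant ROI has no range: every voxel maps to level 1
and the result carries a `degenerate` flag that downstream features honor
(zero contrast, missing correlation, etc.).

### Global (first-order) features

Variance, skewness and kurtosis of the in-ROI intensity *histogram*. The
bin count is the median of three classical rules —

* Sturges: `k = ceil(log2 n) + 1`
* Scott: `h = 3.49 · s · n^(−1/3)`, `k = ceil(range/h)` (s = sample SD)
* Freedman–Diaconis: `h = 2 · IQR · n^(−1/3)`, `k = ceil(range/h)`
  (IQR by linear-interpolation quantiles)

— a compromise that stays reasonable across ROI sizes where any single
rule over- or under-smooths. Degenerate cases (zero SD, zero IQR) warn and
fall back (k = 1, or Sturges respectively). Moments are computed from bin
centers weighted by counts, with population (1/n) normalization; kurtosis
is **non-excess** (Normal → 3). Both choices are switchable
(`binned=False` for raw-voxel moments; `normalization='sample'`), because
the binned-vs-raw and kurtosis conventions are the two most common sources
of cross-package disagreement for these features.

### Second-order (GLCM) features

For each of the 13 canonical unit displacements (one per ± pair of the 26
direct neighbors), ordered in-mask voxel pairs `(v, v+d)` are counted, the
reverse direction added (symmetric accumulation), and the matrix
normalized. Eight features are computed per direction — energy, entropy
(log base 2 by default), contrast, homogeneity, correlation, variance,
sum-average, dissimilarity, with the formulas listed in
`muscletex/glcm.py` — and the unweighted mean over the 13 directions is
reported. Because the 13-direction set maps onto itself under every
axis-aligned rotation, the averaged features are rotation invariant, which
the test suite verifies over all 24 proper cube rotations at double
precision.

Choices worth knowing:

* Displacement is fixed at one voxel (isotropic resampling makes every
  offset a single-voxel step); an optional inverse-length weighting
  (1, 1/√2, 1/√3) of direction contributions is available
  (`glcm.weighting: inverse_length`), as is a pooled mode that merges all
  13 count matrices before computing features once (`glcm.mode: pooled`).
* GLCM variance uses the marginal mean of the symmetrized matrix
  (μ = μ_x = μ_y); sum-average uses the sum histogram `p_{x+y}`.
* Empty rows/columns of the matrix are retained (no level compaction), so
  features are comparable across muscles with different occupied ranges.
* A direction with no valid pair is excluded from the average; correlation
  is missing (NaN) only if the ROI is constant in every direction.

## Synthetic data

No public PDFF + dynamometry dataset exists at this scale, so the package
generates its own study with known ground truth.

**Phantoms.** One muscle compartment is an ellipsoidal cylinder (ellipse
in-plane, extruded through all slices) on a 24 × 24 × 12 grid at
3.2 × 2.0 × 4.0 mm by default (≈ 3800 ROI voxels). Patterns:

* `homogeneous` — spatially uncorrelated Gaussian voxel noise
  (SD 1.0 pp default) around the target mean;
* `streaks` — elongated high-PDFF bands: anisotropic Gaussian noise
  smoothed with σ = (scale, scale, 4·scale) voxels, hard-thresholded at
  the (1 − fraction) in-mask quantile, elevated by an amplitude. Defaults:
  scale 1 voxel (bands ~2 voxels across, a few mm, running along the slice
  axis like fat streaks along muscle fibers), fraction 0.25, amplitude
  2 × the target mean. The hard edges and thin bands are what give streak
  phantoms their higher co-occurrence contrast at matched mean — with
  soft, wide bands the ROI-windowed quantization can make uncorrelated
  noise look *rougher* than structure, and the patterns would not separate;
* `blobs` — the isotropic-σ analog.

After pattern and noise, a global additive offset is fixed-point iterated
so the **post-clip** ([0, 100] %) in-ROI mean equals the target to < 1e-6
pp. A target of exactly 0 with nonzero noise is unreachable under clipping
(the iteration safely bottoms out near the truncated-noise mean). Every
phantom draws from its own `numpy.random.SeedSequence` stream, spawned
from the master seed (one child per subject, one grandchild per
muscle-side phantom), so generation is reproducible and order-independent.

**Cohort.** 30 subjects by default (15 F / 15 M), age ~ N(30, 6) y,
BMI ~ N(27, 2.6) kg/m², two observations per subject (left/right).
Subject-level target mean PDFF: EXT ~ N(3.0, 1.4) %, FLEX ~ N(3.9, 1.9) %
(floored at 0.3 %), with a per-side jitter of SD 0.3 pp. A per-subject
*streak severity* ~ U(0, 1) scales the streak amplitude of that subject's
phantoms (severity 0 ⇒ effectively homogeneous). Strength (MVIC, Nm) is
linear with Gaussian noise:

    MVIC = intercept + 85·[male] + 3·BMI − 8·PDFF − 30·severity + N(0, 15)

with intercepts 100 (extension) / 30 (flexion), shared slopes. These
defaults give extension ≈ 150 (F) / 235 (M) Nm and flexion ≈ 70 (F) /
155 (M) Nm — extension in the physiological range, the flexion male mean
deliberately tied to the shared sex slope (a per-outcome sex effect was
judged not worth the extra parameters). MVIC is floored at 1 Nm to keep
strength positive; under the defaults the floor binds with negligible
probability. The generating coefficients are returned with the table so
recovery tests compare fitted CIs against truth.

**What the generator does not emulate:** MR physics (echoes, T2*,
water–fat swaps, bias fields), multi-muscle anatomy, partial-volume mixing
at the muscle–fat interface, age effects on strength, and any calibration
of the streak geometry to real infiltration texture (no quantitative
description of it exists to calibrate against). Passing tests therefore
demonstrate the *machinery* is correct and that the features separate
constructed patterns at matched mean — not that real muscles exhibit these
effect sizes.

## Statistical layer

* **Screen:** per feature, OLS of MVIC on {sex, side, age, BMI, feature},
  both sides stacked side-matched (n = 2 × subjects). Reported: feature
  term p (two-sided t, identical to the single-df F) and model adjusted
  R². Bonferroni flag at α/m with m = 12 (PDFF + 11 features per
  outcome).
* **Stepwise:** forward entry (smallest p < 0.05) with backward removal
  (p > 0.10), ties broken by candidate order, full audit log; an empty
  final model is valid. No multiplicity correction inside the procedure.
* **Group comparison:** pooled-variance unpaired t-tests (Welch via
  `stats.equal_var: false`), male vs female per side.
* Coding: female = 0 / male = 1, left = 0 / right = 1. The two rows per
  subject are treated as independent with a side fixed effect — the
  within-subject correlation this ignores inflates the screen's precision;
  `stats.cluster_robust: true` switches the screen to cluster-robust SEs
  on subject for sensitivity analysis.

## Numerical and testing choices

* GLCM integer pair counts are compared *exactly* against a brute-force
  triple-loop enumerator on small volumes; features match naive double
  loops to 1e-12.
* Simulation sizes: 50 oracle volumes (≤ 8³, Ng ≤ 8), 10 phantoms × 24
  rotations, 200 stepwise replicates (n = 60, 26 candidates), 100
  mean-matched separability pairs, 500 cohort replicates for CI coverage.
  These give stable Monte-Carlo estimates at interactive runtimes.
* The regression layer is cross-checked against an explicit
  normal-equations solve (independent of the statsmodels path used in
  production).

## Known limitations

* Whether the original texture toolchains window quantization to the ROI
  min/max or to a fixed physical range, and whether they average features
  over directions or pool counts first, are genuinely ambiguous
  conventions; both are implemented, defaults as stated above, and results
  should cite the configuration.
* Global-feature values depend on the data-driven bin count, which jumps
  discretely with ROI size; comparisons across very different ROI volumes
  inherit that discreteness.
* The synthetic strength model is linear by construction; the stepwise
  procedure's behavior on real, nonlinear muscle–strength relationships is
  outside what these simulations can show.
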