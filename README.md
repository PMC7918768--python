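# muscletex

Texture analysis of muscle proton density fat fraction (PDFF) maps, and
the statistics relating texture to muscle strength.

Mean PDFF — the average fat fraction over a segmented muscle — is the
standard MR biomarker of muscle fat infiltration, but it discards how the
fat is *arranged*: a muscle with diffuse, homogeneous infiltration and a
muscle with the same mean concentrated in fat streaks are
indistinguishable by mean alone, yet may differ in function. `muscletex`
computes, per muscle region of interest (ROI):

* **mean PDFF** (percent);
* **3 global histogram features** — variance, skewness, kurtosis of the
  in-ROI intensity histogram, with the bin count chosen as the median of
  Sturges', Scott's and the Freedman–Diaconis rules;
* **8 second-order features** from 3D gray-level co-occurrence matrices
  (GLCM) — energy, entropy, contrast, homogeneity, correlation, variance,
  sum-average, dissimilarity — computed over the 13 unit displacements of
  the 26-neighborhood after isotropic resampling and 200-level uniform
  quantization, then averaged across directions for rotation invariance:

  `p(i,j)` is the joint probability that two in-mask voxels separated by
  displacement `d` carry quantized levels `i, j`; e.g.
  contrast = Σ (i−j)² p(i,j), energy = Σ p², entropy = −Σ p log₂ p.

A statistical layer mirrors the standard study design: covariate-adjusted
single-feature screens (OLS of strength on sex, side, age, BMI + one
feature; adjusted R², F-test p, Bonferroni marking at m = 12), SPSS-style
stepwise selection (enter p < 0.05, remove p > 0.10), and sex-group
t-tests.

Because no public dataset pairs thigh PDFF maps with dynamometry, the
package ships a first-class synthetic generator: muscle-compartment
phantoms with controllable fat patterns (homogeneous noise vs. thin
high-PDFF streaks vs. blobs) at exactly controlled mean PDFF, and a
30-subject cohort whose strength comes from a known linear model — so
every claim the package makes is testable against ground truth. See
`docs/methods.md` for the full model description.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (equivalently: `muscletex run --out results/run --seed 1`):

```sh
python analysis/01_simulate.py --seed 1          # cohort + NIfTI phantoms
python analysis/02_extract_features.py --seed 1  # per-muscle feature table
python analysis/03_analyze.py --seed 1           # regression layer
```

The analysis step prints (seed 1):

```
single-feature screen (adjusted for sex, side, age, BMI):
  mvic_ext: top features by p-value
    correlation        R2_adj=0.908 p=3.665e-06 *
    pdff               R2_adj=0.891 p=0.0004777 *
    kurtosis_global    R2_adj=0.886 p=0.002035 *
  ...
== stepwise model for mvic_ext ==
  step 1: add sex_male (p=1.038e-26)
  step 2: add correlation_ext (p=0.0001334)
  step 3: add bmi (p=0.001557)
  selected: ['sex_male', 'correlation_ext', 'bmi']
  R2_adj = 0.9069, model p = 1.818e-29
```

Reading this: in a cohort whose strength was generated from sex, BMI,
mean PDFF and streak severity, the screen ranks a texture feature
(GLCM correlation of the extensors) above mean PDFF for extension
strength, and the stepwise model keeps sex, that texture feature, and BMI
— texture carries strength information beyond the mean, which is the
package's point. The `*` marks Bonferroni-corrected significance
(p < 0.05/12).

The mechanism probe:

```sh
python analysis/04_pattern_separability.py --seed 1 --pairs 50
```

```
50 mean-matched pairs (max |mean diff| = 0.068 pp)
  streak contrast higher:        100%
  streak global variance higher: 100%
  median contrast ratio streak/homog: 2.51
```

Phantom pairs whose means agree to < 0.1 pp are separated perfectly by
GLCM contrast and global variance — features that see the arrangement of
fat, not its amount.

## Layout

```
src/muscletex/     library: synthetic, preprocess, histfeat, glcm, stats,
                   pipeline, io, cli
analysis/          numbered narrative drivers over the library
scripts/           acceptance.py (see above)
tests/             pytest suite incl. brute-force oracles
docs/methods.md    model, conventions, design choices, limitations
```
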