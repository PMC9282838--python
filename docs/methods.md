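# Methods

## Scope and data model

The package analyses newborn dried-bloodspot methylation cohorts containing a
Down-syndrome (DS) group and a non-DS group. Inputs are a CpG-by-sample beta
matrix in [0, 1] with a per-CpG chromosome annotation, clock coefficient files
(intercept plus per-CpG weights), a 7-cell-type reference of mean betas, a
long-format table of per-sample, per-bin intensity log2 ratios, and a sample
sheet (DS status, sex, gestational age in days, age at blood collection in
hours, birthweight, batch, ancestry PCs, ALL status, GATA1 mutation status and
variant allele fraction where sequenced). Normalisation of raw arrays (noob /
functional normalisation / BMIQ), IDAT parsing, reference-library selection
and ancestry-PC derivation happen upstream and are out of scope: the pipeline
consumes normalised betas and treats the reference CpG set and PCs as inputs.

A deliberate unit choice: *age at blood collection is stored in hours*, and
chronological age from conception is `GA_days + collection_hours / 24`. The
group means used as generator defaults (55.25 and 32.72) only reconcile with
the chronological-age means (269.22, 275.84) under this reading.

## Clocks

A clock is `x = a + Σ_j w_j β_j` over its CpG set. Adult-calibrated clocks
map x to years with `age(x) = 21·exp(x) − 1` for `x < 0` and `21·x + 20`
otherwise (anchor `A = 20`; continuous and strictly increasing, with newborns
on the exponential branch). The anchor follows the calibration convention of
the clock literature; it is the single canonical constant used for both
adult clocks. Gestational clocks return x unchanged, in days.

Missing clock CpGs — whether absent from the matrix (platform differences) or
missing per sample — are filled with that sample's mean over its available
clock CpGs. This per-sample mean rule is the primary, exactly reproducible
path; a k-nearest-neighbour option (scikit-learn's KNNImputer across samples)
is available behind a flag for users who prefer the classical routine. A
sample with zero available clock CpGs is an error, not a guess.

Sensitivity variants drop CpGs from the weight map (never impute them):
`restrict_clock` removes an explicit CpG set and/or all clock CpGs annotated
to a chromosome (chr21 for the trisomy-confounding check, plus any overlap
with the deconvolution reference, computed from the loaded reference rather
than hard-coded).

## Age acceleration

The reference line is OLS of clock output on chronological age over non-DS
samples only; DNAmAA is every sample's residual from that line, so non-DS
mean DNAmAA is identically zero. Samples missing chronological age are
excluded from both the fit and the residual vector, with a logged count.
Day conversion divides a clock-scale estimate (and its CI bounds) by the
reference slope. By default the *unrounded fitted* slope is used; a
`round_day_slope` flag switches to the slope rounded to 3 decimals,
which is the convention under which published day columns (e.g.
0.3477 → 347.7) are exact. Gestational-age acceleration uses a different
anchor: residuals of the gestational clock on observed GA plus DS status,
fitted on all samples (the two anchors coincide when there is no DS effect
and no collection-age variation).

## Cell-type deconvolution

Per sample, weights solve `min ||β − R'w||² s.t. w ≥ 0` (scipy NNLS) against
the cell-by-CpG reference R, then are normalised to sum to 1. The cited
reference-based method leaves totals unconstrained; normalisation is applied
because the proportions enter regressions as compositional covariates. The
high-nRBC flag is strict (`nRBC > 0.25`) and is computed on the normalised
proportions. Granulocytes — the largest compartment — are the dropped
category in all downstream models to avoid simplex collinearity. The
correctness oracle in the test suite is an exhaustive simplex grid search at
0.01 resolution (a 0.05-step enumeration of the full 7-simplex followed by a
0.01-step local refinement), independent of the NNLS path.

## Trisomy-21 calling

Bin-level log2 ratios are `log2(intensity / median reference intensity)` with
a seeded random draw of non-DS reference samples. A sample's chr21 summary is
the median over its chr21 bins (317 by default). Classification, with cohort
statistics recorded in every call: non-DS samples are never elevated; a DS
sample is *likely mosaic/partial* if its median lies more than 2 SD (ddof=1)
below the mean over **all** DS samples (candidates included) while exceeding
the non-DS maximum; otherwise *full T21* if the median is ≥ 0.2; otherwise
*not elevated*, kept with a QC warning rather than dropped. The mosaic rule
takes precedence where the windows overlap — flagged mosaics live below the
full-trisomy threshold. The 0.2 threshold reflects array compression: the
theoretical three-copy shift is log2(3/2) ≈ 0.585, and the generator's
`attenuation` parameter (default 0.5) models the compression, giving full-T21
medians of ≈ 0.29 and mosaic medians `0.5·log2((2+f)/2)` for cell fraction f.

## Inference

All models are OLS (statsmodels) with Wald 95% CIs from the t distribution.
Covariates are screened univariably in the non-DS group at p < 0.2 (overall
F test, so categorical batch is screened as a block); chronological age always
stays in clock-outcome models and never enters acceleration-outcome models.
The ancestry-PC count is the smallest k minimising AIC over nested models
PC1..PCk (ties toward smaller k), with LRT p values reported; clock and
DNAmAA outcomes may legitimately select different k. The model suite mirrors
the study design: base and fully adjusted DS models on the clock and its
DNAmAA, sensitivity subsets excluding high-nRBC newborns or restricting to
GATA1-wildtype DS plus non-DS, CpG-excluded clock variants, gestational-clock
models (GA-adjusted) and their null acceleration models, GATA1 status and
VAF models within sequenced DS (VAF effects convert to days per 10% VAF),
per-cell-type DS models, and bivariate tests (Student's t, chi-squared,
Spearman, Kruskal–Wallis with BH-adjusted pairwise Wilcoxon rank-sum).
p values below 1e-4 are displayed as "<0.0001"; raw values are stored.
Collinear designs fail with the offending columns named. Missing covariates
cause listwise deletion, and reported `n_used` reflects it.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
defaults fixed to the study's reported cohort moments:

| Quantity | DS | non-DS |
|---|---|---|
| n | 346 | 567 |
| GA days (mean, SD) | 266.98, 17.65 | 274.47, 13.93 |
| Collection age hours | 55.25, 49.74 | 32.72, 17.46 |
| Birthweight g | 3029.9, 686.3 | 3386.1, 541.8 |
| Male fraction | 0.541 | 0.584 |
| ALL case fraction | 0.425 | 0.229 |
| High-nRBC fraction | 0.17 | 0.002 |

GA is truncated to [150, 320] days and collection age to ≥ 0; truncated
normals are moment-matched (the underlying location/scale are solved so the
truncated law has the configured mean and SD), keeping sample moments unbiased.
The injected clock signal is
`baseline + 0.001/day · chron_age + 0.24·1[DS] + 1.78·VAF`, with
`baseline = −0.676` chosen so the non-DS mean clock value is ≈ −0.40.
Clock-scale scatter (`noise_sd_clock_years`, default 0.07) reproduces the
non-DS clock SD and hence the weak observed clock–age correlation (R² ≈ 0.03);
`noise_sd_beta` (default 0.003) is per-CpG array noise. GATA1 mutations are
assigned within a sequenced DS subset (53% sequenced, 16.3% positive); VAF for
positives is Beta(0.27, 0.83), solved to reproduce the reported VAF moments
(mean 0.04, SD 0.15) over all sequenced DS including wildtype zeros.
GATA1-positive newborns receive elevated true nRBC proportions — deliberate
confounding structure. Six mosaic fractions (0.25–0.55) are injected by
default, spanning observed mosaic medians of roughly 0.08–0.18 at
attenuation 0.5.

Age-signal embedding distributes a target linear predictor across clock CpGs
proportionally to `w_j / Σ w_k²` around a base beta of 0.5 and clips to
[0, 1] (clips are counted and reported in the truth object). Synthetic clock
weights are mixed-sign, scaled to the smallest magnitude that keeps every
target in roughly (−0.95, 2] years (or [150, 330] days) attainable — small
mixed-sign weights also keep CpG-excluded variants well-behaved, as published
coefficient files are. At zero noise the closed loop (generate → compute)
recovers true epigenetic age to better than 1e−8.

What the generator does **not** emulate: genome-wide CpG correlation
structure outside the clock/reference/chr21 sets, batch-effect chemistry,
probe-level intensities, gestational-clock shrinkage (synthetic gestational
clocks track GA with SD ≥ the GA SD, unlike real predictors), or any real
biological coupling between cell composition and clock CpGs beyond the
injected GATA1–nRBC confounding. Passing tests therefore demonstrate that the
estimators recover the structure they assume — not that real bloodspot data
satisfy those assumptions.

## Numerical and design choices

- Betas outside [0, 1] after upstream processing are rejected at the
  container boundary; the generator clips with a count instead.
- QC order is fixed: detection-p filter (mean p > 0.01), then CpG missingness
  (> 15%), then sample missingness computed over surviving CpGs. Removing
  everything in either dimension is fatal.
- The DS cohort SD in the mosaic rule uses the n−1 denominator.
- BH adjustment uses the standard step-up; note it is not idempotent (only
  constant adjusted vectors are fixed points), so the tests assert
  monotonicity and hand-checked vectors rather than idempotence.
- Simulation problem sizes in the test suite are scaled to the check at hand:
  study-scale cohorts (346/567) where cohort moments matter, 200+200 over 200
  replicates for CI-coverage calibration, 60+60 over 1000 replicates for
  type-I error, 50 replicates for mosaic detection.
- The recovery/calibration experiments disable the GATA1 effect
  (`gata1_fraction_ds = 0`): with carriers present the DS coefficient absorbs
  the VAF contribution by design — that is injected confounding, not
  estimator error.

## Known limitations

- Real published clock coefficient files are not bundled; all built-in clocks
  are synthetic (CpG counts 391/353/176/148/96 match the published clocks).
  Real coefficient CSVs load through the same `cpg_id,weight` schema.
- Mosaic vs partial trisomy cannot be distinguished from bin medians; the
  classifier emits a single combined label.
- The pipeline assumes one cohort per run; meta-analysis across cohorts and
  mixed-effects batch handling are out of scope (batch is a fixed effect).
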