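# Methods

## Problem and pipeline

The package studies whether the echotexture of B-mode breast ultrasound
carries enough information to predict a patient's percentage mammographic
density (PMD) — the fraction of radiologically dense, fibroglandular area on
a mammogram.  The pipeline is:

1. **ROI**: in each of a patient's five images (one retro-mamillary view,
   one per quadrant), the breast tissue between the skin line and the
   pectoral muscle is the region of interest.  The largest axis-aligned
   rectangle fully inside the ROI mask is selected for measurement.
2. **Features**: a 256-level gray histogram is computed over each rectangle;
   the five histograms are pooled by summing counts, giving one combined ROI
   per patient.  The pooled histogram is reduced to 16 equal-width gray-level
   bins (percentages of ROI pixels), ordered white (bin 1, gray values
   240–255) to black (bin 16, gray values 0–15).  The 16 percentages sum to
   100 by construction, so the darkest bin is redundant and omitted; bins
   1–15 are the predictors.
3. **Models**: eight regression models of PMD on the 15 bins — null (M0),
   OLS (M1), OLS with backward selection (M2), natural cubic splines with
   2 df per bin (M3), splines with backward selection of whole term groups
   (M4), lasso (M5), ridge (M6), random forest (M7).
4. **Evaluation**: apparent metrics (fit and score on the full data) versus
   100×3-fold repeated cross-validation, where each model's entire fitting
   procedure — selection, knot placement, standardisation, penalty tuning —
   is repeated inside every training fold.  The model with the smallest
   cross-validated MSE is the final model, illustrated on a single random
   2/3–1/3 hold-out split.

PMD is carried on the 0–1 fraction scale throughout; only displays use
percent.  On the fraction scale the null model's apparent MSE equals the
outcome variance, which makes the null row of the report directly
interpretable.

## Metrics

`MSE` is the mean squared residual.  `R² = 1 − MSE / Var(y)` with the
population-variance divisor *n*; on training data with least-squares fits it
lies in [0, 1], while on held-out data it can be negative (predicting worse
than the fold mean).  Cross-validated metrics are computed per held-out fold
— including the fold-local variance in R² — and averaged over all
repeats × folds records.  A pooled alternative (pool all out-of-fold
residuals of a repeat, then average over repeats) is switchable via
`CVConfig(aggregation="pooled")`; the two differ only slightly at these fold
sizes, and the fold-local rule is the default because the per-fold records
it averages are also what the report stores.  The partition RNG stream is
separate from the model RNG streams, so every model sees identical fold
partitions within a repeat.

## Model-fitting conventions

Choices the model list leaves open were fixed as follows:

* **Backward selection (M2, M4)** greedily drops the term whose removal
  lowers the Gaussian AIC, `n·log(RSS/n) + 2k`, until no drop helps — the
  convention of R's `step`.  M4 drops whole 2-column spline groups, never
  single basis columns, so a predictor is either fully in or fully out.
* **Splines (M3, M4)**: natural (restricted) cubic splines with 2 degrees
  of freedom per predictor — boundary knots at the training minimum and
  maximum and one interior knot at the training median, in Harrell's
  truncated-power form.  The basis contains the linear term, so M1 is
  nested in M3.  Validation rows are expanded with the training knots; a
  constant training column degenerates to the column plus a zero column.
* **Penalised models (M5, M6)**: predictors are standardised with training
  means and standard deviations.  The penalty grid has 100 log-spaced
  values spanning six orders of magnitude below the data-driven maximal
  penalty `max|Xᵀ(y−ȳ)|/n` (for the ridge, inflated by 10³ since no finite
  ridge penalty annihilates the fit — glmnet's convention).  The penalty
  minimising inner 10-fold CV MSE is chosen and the model refit on the full
  training data.  The ridge path is evaluated through a single SVD per
  inner fold, which makes the 100-point grid essentially free.
* **Random forest (M7)**: 500 trees, 5 candidate predictors per split
  (⌊15/3⌋), minimum node size 5.  "Minimum node size" follows the
  regression-forest convention in which it gates whether a node may be
  split (children may be smaller), i.e. `min_samples_split = 6`; the
  stricter leaf-size reading caps the apparent fit well below what deep
  regression forests show on cohorts of this size.
* **Predictions are not clipped** to [0, 1] by default: the reported
  MSE/R² refer to raw model output.  `clip_predictions` is available per
  model for applications that need bounded densities.

Degenerate designs (rank-deficient after selection) fall back to the
minimum-norm pseudo-inverse solution with a logged warning.

## Synthetic cohort

No imaging cohort ships with the package, so a generator emulates the study
conditions with full ground truth:

* **Latent density** *d* ~ Beta, moment-matched to mean 0.422 and variance
  0.0396 (shape parameters ≈ 2.18 and 2.98).  A Beta prior is the minimal
  bounded-support choice reproducing the reported mean/median/IQR pattern
  of PMD (median ≈ 0.43, quartiles ≈ 0.28/0.56).
* **Outcome**: two simulated readers perturb *d* with Gaussian noise
  (sd 0.03), truncated to [0, 1]; their average is `pmd_observed` — the
  quantity every model predicts.
* **Images**: five 400×400 8-bit views per patient.  Rows above a sampled
  skin line are bright skin (gray 220), rows from a sampled muscle line
  down are dark muscle (gray 40).  Between them, a standard-normal field
  smoothed at `blob_scale` = 6 px is thresholded at an empirical quantile
  to give a spatially correlated two-tissue texture: bright
  fibroglandular-like pixels (mean gray 170) with fraction
  `p = signal_strength·d + (1 − signal_strength)·0.5` plus a per-view
  Gaussian perturbation (`view_sd`), and dark fat-like pixels (mean gray
  80) otherwise.  Every pixel is multiplied by gamma speckle with unit
  mean and shape 4 (intensity CV 0.5), rounded and clipped to [0, 255].
  The ROI mask marks exactly the rows strictly between the skin and muscle
  lines.
* **Signal calibration**: the defaults `signal_strength = 0.2`,
  `view_sd = 0.12` place the cohort in the weak-to-moderate regime the
  emulated study reports — per-bin Spearman |ρ| up to ≈ 0.3–0.6,
  best cross-validated R² around 0.15–0.3, and a random forest whose
  apparent R² (~0.85) far exceeds its cross-validated value.  With
  `signal_strength = 0` the texture is uninformative (a null-control
  setting); with 1 the bright-pixel fraction is fully determined by *d*.
* **Determinism**: all outputs are pure functions of the config and seed.
  Patients draw from spawned child streams of the seed, so cohorts of
  different sizes share their leading patients.

What the generator does **not** emulate: depth-dependent attenuation and
focal-zone effects, anisotropic speckle, curved skin/muscle interfaces,
operator-dependent probe pressure, device presets, lesions, and the
two-investigator ROI annotation of real studies (a single mask per image is
emitted; how two annotations would be merged is left open).  Passing
recovery tests therefore show that the pipeline is correct and unbiased
under its own generative assumptions, not that ultrasound texture predicts
mammographic density in the clinic.

## Numerical choices and edge cases

* Gray histograms are exact integer counts; bin percentages are carried at
  full float precision (conservation to 1e−9 is asserted, not rounded in).
* `largest_rectangle` uses the row-stacked histogram method (O(rows·cols),
  numba-compiled); area ties break deterministically by smallest top row,
  then smallest left column, then largest height.  Coordinates are 0-based
  and half-open.
* Empty ROI masks raise an explicit error (an unusable image should fail
  loudly, not contribute an empty histogram).
* Spearman ρ uses average ranks for ties; a constant bin is reported as
  missing with a warning rather than as 0.
* The lasso path is solved with a precomputed Gram matrix and a 2 000
  iteration cap; at the tiniest grid penalties on strongly collinear bins
  the coordinate-descent fits may stop early, which leaves the selected
  penalty unchanged while keeping the inner CV fast.
* The 2/3–1/3 hold-out split takes ⌊2n/3⌋ training patients.

## Problem sizes in the shipped checks

The test suite runs the full study scale where it matters (168 patients,
eight models) with 2–20 CV repeats, and reserves the 100-repeat protocol
for the analysis scripts; the brute-force rectangle oracle covers 500
random masks up to 12×12, and generative-recovery checks use feature-level
cohorts of 500 patients with a constructed population R².

## Known limitations

* The generator's gray-level geometry is far cleaner than clinical B-mode
  data; absolute metric values depend on the calibration above and should
  not be read as clinical performance.
* AIC-based backward selection is greedy and need not find the AIC-optimal
  subset.
* The inner penalty CV standardises once on its training data (glmnet's
  behaviour) rather than re-standardising per inner fold.
* With 3 folds and 168 patients, fold-local variances are stable; for much
  smaller cohorts the pooled aggregation rule is preferable.
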