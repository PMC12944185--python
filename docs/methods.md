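# Methods note

`kineticrad` implements a kinetic-curve parametric radiomics workflow for
predicting breast-cancer molecular subtypes (HR+/HER2−, HER2+, TNBC) from
dynamic contrast-enhanced MRI (DCE-MRI). This note records the model, its
assumptions, the main numerical choices and their limitations.

## Kinetic parametric maps

Each patient contributes one pre-contrast volume and N ≥ 3 registered
post-contrast volumes at strictly increasing times t₁ < … < t_N (seconds
after contrast injection). Voxel intensities are normalized by the
pre-contrast value, sᵢ = Iᵢ / I_pre, giving a unitless time-intensity
curve (TIC) anchored at s = 1.

Two semi-quantitative parameters summarize each voxel's TIC:

- **Wash-in rate (WIR)**: `(s_peak − 1) / t_peak`, where the peak is the
  maximum of the first three post-contrast phases (ties resolved to the
  earliest phase). Units s⁻¹. Restricting the peak search to early phases
  captures the upslope and is robust to late washout.
- **TIC-Area**: the trapezoidal integral of the normalized curve over
  `(0, 1), (t₁, s₁), …, (t_N, s_N)`, divided by t_N. Unitless; a constant
  non-enhancing voxel yields exactly 1.

Voxels with a non-positive or vanishing pre-contrast value are flagged as
degenerate, mapped to 0 and counted in the map's QC metadata.

## Feature extraction

Both parametric maps and the peak-enhancement phase image (the "MR-ORI"
baseline, the single post-contrast phase with the highest mean in-mask
normalized enhancement) are processed identically:

1. **Resampling** to isotropic 1 mm³ — cubic B-spline for the image,
   nearest-neighbour for the mask. The output grid keeps every voxel
   centre inside the input physical extent, so no extrapolated values
   enter the features.
2. **Wavelet filtering**: undecimated single-level separable 3D transform
   (coif1, symmetric-reflection boundaries), producing 8 bands labelled
   `LLL…HHH` (the letter at position i is the low/high-pass filter applied
   along axis i in (x, y, z) order).
3. **Discretization** with a fixed bin width, min-anchored:
   `level = floor((v − min) / w) + 1`. This makes all texture features
   invariant to adding a constant to the intensities.
4. **Features**: 14 shape features (mask only, computed once), and per
   image (original + 8 bands) 18 first-order features plus 75 texture
   features across five families — GLCM (24), GLRLM (16), GLSZM (16),
   NGTDM (5), GLDM (14) — following the IBSI-aligned reference
   definitions. Total: 14 + 9 × 93 = **851 features per image**.

Texture conventions: GLCM is symmetric, distance 1, averaged over the 13
unique 3D directions (directions without pairs are excluded from the
average); GLRLM is averaged over the same 13 directions; GLSZM zones are
26-connected; GLDM dependence counts the centre voxel plus its in-ROI
Chebyshev-1 neighbours within the level tolerance α = 0; NGTDM includes
voxels with at least one in-ROI neighbour. Degenerate single-level ROIs
use the reference conventions (Skewness/Kurtosis reported as 0, GLCM
Correlation and MCC as 1, NGTDM Coarseness capped at 10⁶).

**Bin widths.** A fixed bin width of 5 is conventional for raw
MR signal but collapses a kinetic map (values of order 10⁻² s⁻¹ or a few
units of normalized area) to a single gray level. The pipeline therefore
applies per-source widths scaled to each image's value range: 0.0005 for
TIC-WIR, 0.02 for TIC-Area, 5.0 for MR-ORI. This preserves the fixed-bin-
width rule (translation invariance, comparable level counts) while keeping
the texture matrices informative on all three sources.

## Feature selection

Selection is fitted on the training split only and then frozen:

1. **Variance filter**: drop features with raw sample variance < 0.01
   (applied pre-standardization; on z-scored data the threshold would be
   vacuous).
2. **Correlation pruning**: while any pair has |Pearson r| > 0.8, take the
   largest-|r| pair and drop the member with the higher mean absolute
   correlation to the remaining features (ties drop the later column).
3. **LASSO**: multinomial L1-penalized logistic regression on z-scored
   features; penalty chosen by stratified 10-fold cross-validated log
   loss; kept features are the union of nonzero supports across classes.
   Fold count is clamped to the smallest training class when necessary.

## Models

- **Base models** (one per image source): one-vs-all gradient-boosted
  trees realized as K independent binary LightGBM classifiers — the
  library offers no literal one-vs-all multiclass loss, and independent
  binary models match those semantics exactly. Each sample is weighted by
  the square-root-balanced weight of its class, w_c = √(max_k n_k / n_c).
- **Calibration**: per-class isotonic regression fit on training
  predictions (pool-adjacent-violators; exact monotone least squares).
- **Fusion**: a LightGBM model of the same family over the 6 calibrated
  per-class probabilities of the TIC-WIR and TIC-Area base models.
  Calibrated probabilities are deliberately *not* renormalized before
  fusion — they are features there, and renormalization would destroy the
  marginal calibration. Only `predict_proba`, which returns class
  distributions, normalizes rows.
- **Cross-fitted fusion inputs**: the meta-learner is trained on
  stratified 5-fold out-of-fold calibrated probabilities of the base
  models, not their in-sample predictions. Boosted trees can memorize a
  small training cohort, in which case in-sample calibrated probabilities
  collapse to the one-hot labels for every source and the fusion model is
  blind to which channel carries real signal; out-of-fold inputs (standard
  stacked generalization) restore honest training-time features. At
  prediction time the fusion consumes the full-data base models'
  calibrated probabilities.

Boosting defaults are 300 trees, learning rate 0.05, depth 6, no early
stopping: at the cohort sizes this package targets a 10% early-stopping
holdout would be too small to be useful, so capacity is controlled by the
fixed iteration budget instead.

## Evaluation

- AUCs are empirical Mann–Whitney statistics (ties count ½): per-class
  one-vs-rest AUCs, their mean (macro), and the AUC of the flattened
  (sample, class) binary problem (micro).
- **DeLong** variances and paired tests use the placement-value
  (structural component) formulation. Comparisons of micro-average AUCs
  treat the flattened scores as paired units, which ignores within-patient
  correlation across classes — a known caveat of micro-level testing.
- **Bootstrap CIs** are percentile intervals over 1000 patient-level
  resamples; resamples missing a class are skipped, and more than 10%
  skips raises an error at the statistics layer. The report assembler
  degrades gracefully (NaN interval plus a logged warning) so that small
  validation splits do not abort a pipeline run.
- **Attributions**: exact TreeSHAP values from the boosted trees
  (`pred_contrib`), additive on the log-odds scale with local accuracy;
  summarized as mean |attribution| per feature per class.

## Synthetic phantom

The phantom generator provides ground truth for end-to-end validation.
Each patient is an ellipsoidal enhancing lesion (≥ 200 voxels) in a
non-enhancing background on a 40×40×28 grid at 1 mm³, five post-contrast
phases at 60–300 s. In-lesion voxels follow a piecewise-linear normalized
curve

    s(t) = 1 + a_v · min(t, t_peak)/t_peak + slope_v · max(0, t − t_peak),

with a_v = wir_v · t_peak. Because t_peak coincides with a sampled phase
within the first three and slopes are non-positive, the WIR map recovers
wir_v *exactly* and the TIC-Area map equals its closed-form integral —
machine-precision oracles for both maps. Voxel-level heterogeneity is
Gaussian-filtered white noise on the kinetic parameters with per-class
correlation length and relative amplitude, giving the texture families a
real signal. The three default classes share a common peak amplitude but
differ in time-to-peak, washout and heterogeneity, so class information
lives in the kinetic maps rather than in any single phase image.

**Realism limits.** The phantom is a validation instrument, not a tissue
simulator: TICs are piecewise-linear rather than pharmacokinetic,
lesions are ellipsoids, the background does not enhance, noise is
Gaussian and uncorrelated across phases, and no registration error,
coil-profile bias or partial-volume effect is modelled. Absolute AUCs on
phantom cohorts therefore say nothing about clinical performance; only
ordering and recovery properties are meaningful.

## Limitations

- Clinical claims are out of scope: no patient data are included, and no
  empirical statement is made here beyond what the test suite computes.
- The micro-average DeLong comparison inherits the flattening caveat
  described above.
- Isotonic calibration is fit on training predictions (no inner
  cross-fitting), which can be optimistic for very flexible base models.
- The per-source bin widths are a pragmatic adaptation of a fixed-width
  rule across value scales; level counts are comparable but not identical
  across sources.
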