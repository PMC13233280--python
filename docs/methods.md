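# Methods

`deltarad` implements a longitudinal delta-radiomics analysis for serial
cone-beam CT (CBCT): radiomic features extracted daily from an organ-at-risk
region (the supraglottic larynx in the motivating application) are aggregated
into weekly means, expressed as ratios to the first-fraction baseline,
de-duplicated by rank correlation, ranked by Random-Forest permutation
importance, and fed to small logistic models whose discrimination of a binary
toxicity outcome is estimated by repeated resampling. This note records the
model, the defaults, and the design choices that were genuinely open.

## Feature extraction

Images and masks are resampled to isotropic spacing (default 1.0 mm;
trilinear for the image, nearest-neighbor for the mask) and in-ROI
intensities are discretized to gray levels `1..Ng`. The default is a fixed
bin count of `Ng = 32`:

```
level(x) = 1 + floor((x - min) * Ng / (max - min + eps)),  clipped to [1, Ng]
```

with `eps = 1e-10 * (max - min)` so the maximum maps to `Ng`; a fixed bin
width mode is available. Discretization is monotone, and a constant ROI maps
to a single level (valid, not an error). No intensity normalization,
resegmentation or outlier clipping is applied before discretization.

The registry holds 43 features: 9 first-order ("Global") statistics, 6 GLCM,
13 GLRLM, 9 GLSZM and 5 NGTDM texture features, plus the ROI volume as an
explicit geometric descriptor. Texture conventions:

* **GLCM / GLRLM** — counts accumulated over the 13 unique distance-1
  direction offsets in 3D and *summed into one matrix before normalization*
  (the "merged" aggregation), rather than averaging per-direction feature
  values. One convention, applied everywhere, with the offset list exposed
  for restricted-direction computation.
* **GLSZM** — zones are 26-connected components of equal gray level.
* **NGTDM** — 26-neighborhoods; per-level `s_g` sums `|g - mean(valid
  neighbors)|` over ROI voxels with at least one valid neighbor. Coarseness
  is capped at `1e6` when `sum(p_g * s_g) = 0` (perfectly flat region).
* **First order** — population moments on the raw in-ROI intensities;
  skewness and excess kurtosis are defined as 0 when the ROI is constant
  (avoids NaNs propagating into ratios); entropy uses the discretized
  histogram (log2).

Every texture feature is checked against an independent brute-force
enumeration oracle (exhaustive pair / run / zone / neighborhood scans written
as plain loops) on random ROIs up to 5x5x5, to 1e-10 relative.

## Volume adjustment

Non-uniformity sums (GLRLM RLN and GLN, GLSZM GLN and ZSN, NGTDM Strength)
grow roughly linearly with ROI voxel count; they are replaced by `-VN`
variants equal to the raw value divided by the voxel count. NGTDM Coarseness
and Busyness scale approximately inversely / linearly with region size and
receive the feature-volume normalization (`-VNF`): Coarseness x voxels,
Busyness / voxels. The exact exponents are a design choice (the normalization
literature the application area cites does not pin a single form); the rule
table is configurable, and the chosen forms are validated empirically by a
tiling test — doubling a self-similar texture roughly doubles raw RLN while
moving RLN-VN by < 10%. ROI volume itself is kept untouched as its own
feature, so anatomical size remains directly modelable. Replacement preserves
the 43-feature count and registry order.

## Weekly aggregation and deltas

Fractions are grouped into fixed blocks of `fractions_per_week = 5` (35
fractions → 7 weeks). For feature `i`, week `w` with `N_w` usable fractions:

```
Xbar[i,w]  = (1/N_w) * sum_f X[i,w,f]
delta[i,w] = Xbar[i,w] / X[i,1]
Xbar[i,W]  = (1/|W|) * sum_{w in W} Xbar[i,w]      (equal week weights)
delta[i,W] = Xbar[i,W] / X[i,1]
```

The baseline is the *fraction-1* value (same modality as every later scan),
so week 1's mean includes the baseline fraction and `delta[i,1] != 1` in
general. Grouped windows average weekly means with equal weights, not pooled
fractions, so unequal `N_w` do not bias the window mean. Missing-data policy:
a week needs at least 3 of 5 fractions (configurable) or it is a missing
cell; a patient missing any week of a grouped window is excluded from that
window with a logged reason. Baselines with `|X[i,1]| < 1e-12` invalidate the
cell (logged) instead of being clipped — ratio deltas are unstable for small
denominators, and silent clipping would hide that. Deltas are scale-free:
multiplying a patient's whole trajectory by any c > 0 leaves them unchanged.

## Feature selection

Per temporal window (selection is re-run independently per window):

1. **Spearman filter** — while any surviving pair has |rho| *strictly* above
   0.8 (equality is retained), the worst-offending pair is located (row-major
   first maximum for determinism) and the member with the higher mean |rho|
   to the other survivors is dropped; ties keep the earlier registry entry.
   Constant features (undefined rho) are treated as rho = 0 with a warning
   and survive.
2. **RF ranking** — 500 bagged Gini-split trees with sqrt feature subsampling
   per node. Importance is out-of-bag *permutation* importance: for each
   tree, the increase in misclassification error on that tree's out-of-bag
   patients after permuting one feature, averaged over trees, raw (not
   divided by its between-tree spread). Impurity-based importances are
   deliberately not used. The "positive set" is the features with importance
   strictly > 0.

## Models and evaluation

Incremental models use the top-K ranked positive-importance features,
K = 1..min(7, positive set size). Each model is a plain maximum-likelihood
logistic regression (logit link, intercept, no penalty). Evaluation is
repeated random two-thirds resampling: `floor(2n/3)` patients (28 of 43)
drawn without replacement and without class stratification, the model fit on
that subset, and predictions generated **for all patients**; the AUC
(midrank/trapezoidal tie convention) is computed per iteration, and 1000
iterations give the mean and the empirical 2.5th–97.5th percentile interval.
Design points:

* Scoring all patients includes the training subset, so the estimate carries
  train-set optimism; this is the stated evaluation design, and a
  `holdout_only` mode is provided as the honest alternative.
* Training draws that contain a single class are redrawn (and counted), so
  the iteration count is exactly as configured.
* Perfectly separated fits do not converge to finite coefficients; the fit is
  kept (probability ranks are still valid for AUC) and counted.
* Optimal K maximizes mean AUC with ties to the smaller K (parsimony).
* Threshold metrics (sensitivity / specificity / accuracy at p >= 0.5) are
  aggregated the same way.

## Stability diagnostics

For each feature, the patients x weeks matrix of single-week deltas yields an
ICC-like index — the one-way random-effects ICC(1,1),
`(MSB - MSW) / (MSB + (k-1) MSW)`, clipped to [0, 1] — plus the mean
within-patient SD and CV across weeks (patient means below 1e-8 in magnitude
are excluded from CV rather than producing unbounded values). ICC(1,1) was
chosen as the simplest one-way form consistent with repeated weekly
measurements; weekly granularity is the default. These are contextual
diagnostics only: no feature is excluded on stability grounds, and the
pipeline's selection and model outputs are bit-identical with the stability
stage disabled (asserted by test).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
CBCT physics. Feature mode draws

```
X[p,i,f] = b[p,i] * d[class(p), i]^(week(f)-1) * eps[p,i,f]
```

with patient baselines `b` lognormal (sigma 0.3), class-linked *drift rates*
`d` (so baseline-anchored ratios carry the signal), and unit-mean lognormal
day-to-day noise with CV `noise_cv`. Multiplicative noise is the natural
partner of a ratio delta: the planted signal is scale-free. Defaults define
the study conditions: 43 patients, 35 fractions, 5 fractions/week, prevalence
15/43, `noise_cv = 0.05`, and planted drifts Global Skewness 1.00 / 1.05
(tolerable / significant) with GLCM Homogeneity 1.00 / 0.98. With these
values the Weeks 1–4 skewness delta separates the classes by about 1.5
pooled SD (class means 1.000 vs 1.078, delta SD ≈ 0.051 ≈ noise_cv x
sqrt(1 + 1/20)), a planted-signal strength chosen before any acceptance
measurement. Labels are assigned deterministically (first ceil(n x
prevalence) patients of a seeded shuffle), making the prevalence exact.

Image mode emits per-fraction volumes with an ellipsoidal ROI whose in-ROI
intensities follow a skew-normal with a per-week shape schedule (the closed
form mapping shape → skewness is `skewnorm_sample_skewness`; recovery is
tested empirically) and whose volume follows a per-fraction shrink schedule;
the background is a distinct Gaussian.

What the generator does **not** emulate — and what passing tests therefore do
not establish about real data: inter-feature correlation (real texture
families are strongly redundant; synthetic features are independent, so the
Spearman filter removes nothing on default cohorts), scanner/reconstruction
heterogeneity, contouring variability, registration error, and any
non-multiplicative drift.

## Determinism and numerics

All randomness flows from integer seeds through `numpy.random.SeedSequence`;
the pipeline spawns per-stage child seeds from one master seed in a fixed
order, so two runs with the same master seed produce byte-identical reports
(manifests record the seed and a config hash, and deliberately no
timestamps). Known float-precision caveat: decision-tree construction is
order-invariant only in exact arithmetic, so a monotone rescaling of a
feature can reorder *near-zero* importances; informative-feature ranks and
importance magnitudes are stable and that is what the property tests assert.

## Problem sizes

Texture oracle equivalence uses 100–120 random ROIs up to 5x5x5; selection
recovery uses 100 replicates of n = 200 with 500 trees; modeling calibration
uses 20 paired null/planted replicates of the default 43-patient cohort at a
200-iteration resampling setting; the full-scale pipeline (1000 iterations)
is exercised by `scripts/acceptance.py`. The calibration tests evaluate a
prespecified three-feature model, paired between null and planted cohorts,
so they measure the optimism of the resampling evaluation itself rather than
the additional optimism of cohort-wide feature selection (which the pipeline,
like the design it follows, performs before resampling — a known source of
optimistic bias that the holdout mode and this note flag explicitly).

## Limitations

No DICOM ingestion, deformable registration, or contour propagation (inputs
are NIfTI image/mask pairs or precomputed feature tables); no 2D or filtered
(wavelet/LoG) feature variants; no harmonization; no difference-based delta
formulations; no clinical or dosimetric covariates; no external-validation
harness. Reported AUCs on synthetic cohorts characterize the pipeline's
behavior under its own generative assumptions, not clinical performance.
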