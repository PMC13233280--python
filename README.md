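# deltarad

Longitudinal CBCT delta-radiomics for early radiotherapy-toxicity modeling.

During fractionated head-and-neck radiotherapy a cone-beam CT (CBCT) is
acquired at every treatment fraction for setup verification. Those ~35 serial
volumes are a free longitudinal record of normal-tissue change, and early
tissue change in swallowing structures (e.g. the supraglottic larynx)
plausibly precedes late dysphagia. `deltarad` is a tested, reusable pipeline
for asking that question quantitatively: it extracts IBSI-style radiomic
features from serial image/mask pairs, tracks their *relative change* over
treatment weeks, and evaluates how well small logistic models on those
changes discriminate a binary toxicity outcome (tolerable vs significant
dysphagia). It is aimed at medical-physics and imaging-biomarker researchers
who want the full chain — extraction through resampled model evaluation — as
auditable, deterministic code, with a synthetic-cohort generator standing in
for patient data.

## The method

Per patient and fraction, 43 features are computed (9 first-order, 6 GLCM,
13 GLRLM, 9 GLSZM, 5 NGTDM, plus ROI volume); size-dependent non-uniformity
features are replaced by volume-adjusted variants (`RLN-VN = RLN / N_voxels`,
`Coarseness-VNF = Coarseness × N_voxels`, ...). Daily values are averaged
over fixed five-fraction blocks (treatment weeks) and anchored to the
fraction-1 baseline:

```
X̄_{i,w} = (1/N_w) Σ_f X_{i,w,f}          weekly mean of feature i
Δ_{i,w} = X̄_{i,w} / X_{i,1}              single-week delta
Δ_{i,W} = (1/|W|) Σ_{w∈W} X̄_{i,w} / X_{i,1}   grouped-window delta
```

The ratio form is scale-free across patients and scanners. Per temporal
window (defaults: Week 2, Weeks 1–4, Weeks 1–6), features with pairwise
Spearman |ρ| > 0.8 are de-duplicated; survivors are ranked by Random-Forest
(500 Gini trees) out-of-bag **permutation** importance — the raw increase in
OOB classification error after permuting one predictor. Logistic models on
the top-K ranked features (K = 1..7) are evaluated by 1000 iterations of
random two-thirds resampling: fit on 2n/3 patients, predict all patients,
record the AUC; reported as mean with the empirical 2.5th–97.5th percentile
interval. Per-feature stability diagnostics (one-way ICC(1,1),
within-patient CV/SD of the weekly deltas) are computed as context, never as
an exclusion rule.

See `docs/methods.md` for conventions, defaults, and known limitations.

## Worked example

Simulate the default synthetic cohort (43 patients × 35 fractions, 15/43
positive, class-linked skewness drift) and run the whole pipeline at a
reduced 200-iteration setting:

```python
from deltarad import PipelineConfig, SyntheticCohortSpec, run_pipeline

cfg = PipelineConfig(cohort=SyntheticCohortSpec(), seed=1, n_iterations=200)
summary = run_pipeline(cfg, "results/demo")
for label, win in summary["windows"].items():
    print(f"{label:9s}  AUC {win['mean_auc']:.3f} "
          f"[{win['ci'][0]:.3f}, {win['ci'][1]:.3f}]  K={win['optimal_k']}  "
          f"top: {win['top_feature']} ({win['top_importance']:.3f})")
```

prints

```
Week 2     AUC 0.748 [0.648, 0.788]  K=7  top: NGTDM Coarseness-VNF (0.012)
Weeks 1-4  AUC 0.838 [0.838, 0.838]  K=1  top: Global Skewness (0.033)
Weeks 1-6  AUC 0.956 [0.874, 0.969]  K=2  top: Global Skewness (0.075)
```

Reading: the planted skewness drift is recovered as the top-ranked predictor
once multi-week aggregation suppresses day-to-day noise, and discrimination
improves from Week 2 to the grouped windows. (A K = 1 model scored on *all*
patients has a degenerate CI: with one feature the predicted probabilities
are monotone in that feature, so every resample yields the same AUC.) The
run directory contains per-window JSON reports, delta / correlation /
importance / per-iteration-AUC CSVs, a stability report, an exclusion log,
and a manifest; rerunning with the same seed reproduces every file
byte-for-byte.

The same pipeline accepts real data: a directory of
`<pid>_f<NN>_img.nii.gz` / `<pid>_f<NN>_mask.nii.gz` pairs plus an
`outcomes.csv` (`images_dir=...`), or a precomputed fraction-level feature
CSV (`features_csv=...`), bypassing extraction. Everything is also exposed
as a CLI:

```sh
deltarad simulate --seed 1 --out cohort/
deltarad run --config pipeline.yaml --out results/
deltarad extract --images scans/ --out features.csv
```

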