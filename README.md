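# levoresp

Predicting levodopa-challenge response from T1-weighted MRI.

The levodopa challenge test (LCT) measures how much a Parkinson's patient's
motor score (MDS-UPDRS III) improves after a levodopa dose:

```
improvement rate = (OFF − ON) / OFF × 100 %
```

A rate ≥ 30 % labels the record a **good** responder, otherwise **bad** —
the label that guides decisions such as deep-brain-stimulation candidacy.
`levoresp` implements, end to end, a machine-learning pipeline that predicts
this label from a pre-registered T1-weighted volume plus routine clinical
covariates, and quantifies how much the imaging actually contributes:

1. **cohort** — response labeling, inclusion filtering (calculable LEDD,
   unique visit, OFF ≥ 5, LEDD ≤ 5000 mg/day), and participant-grouped
   8:2 train/test splitting.
2. **Four imaging feature extractors**
   - *Gray-matter intensity*: 8 mm FWHM smoothing, per-voxel age correction
     fitted on healthy controls, a voxelwise Welch-t discriminative mask
     (p < 0.001), PCA to 50 components.
   - *Subcortical texture*: 32-level quantization per ROI, first-order plus
     gray-level dependence (GLDM) and size-zone (GLSZM) matrix features
     (e.g. LargeDependenceHighGrayLevelEmphasis = Σ P(i,j)·i²·j² / N_z) over
     16 subcortical ROIs, with |r| > 0.9 correlation pruning.
   - *Morphological network*: per-subject graph whose nodes are atlas ROIs
     and whose edge weights are exp(−JS) of the ROIs' intensity histograms;
     features are Onnela weighted clustering and degree centrality per node.
   - *Deep extractor*: a fixed 3D residual CNN (512 channels, overall output
     stride 8) whose segmentation head is replaced by max-pool(kernel 8,
     stride 8, padding 0) + flatten — 13,824 features for a 193×229×193
     volume. Implemented in pure numpy (im2col + BLAS), inference-only,
     with pluggable weights; a `tiny-cnn` profile serves desk-scale volumes.
3. **feature selection** — sequential mRMR (top 50, MID criterion) → LASSO
   (α\* by 5-fold CV, non-zero coefficients) → RFE (L2-logistic estimator,
   CV-chosen count), repeated with reseeded folds and aggregated by
   intersection.
4. **modeling** — imaging / clinical / union feature sets × {SVM, XGBoost,
   MLP}, min–max scaling fitted on training rows only, seeded 5-fold CV
   hyperparameter search, micro-averaged test AUC, and a paired one-tailed
   t-test of union > clinical over the seed ensemble.
5. **saliency** — Grad-CAM seeded at the flatten layer: selected features
   get their importance (excluded positions −0.001), the gradient is routed
   back through pool/flatten to the last convolution, and the rectified
   channel-weighted activation map is upsampled, thresholded at 0.4, and
   reported as 26-connected clusters with per-ROI overlap fractions.

Real LCT imaging cohorts are access-restricted, so the package ships a
first-class **synthetic_data** module generating atlas-labeled volumes with
planted class effects (ROI intensity shift *d*, texture variance inflation,
a global age→intensity trend) and clinical tables matching the demographics
of a real training cohort (age 64.12 ± 9.22 y, LEDD 645 ± 427 mg/day,
MDS-UPDRS III OFF 27.5 ± 12.4, …). Every downstream stage is tested against
this generator.

## Worked example

```python
from levoresp.synthetic import SyntheticConfig, generate_cohort
from levoresp.pipeline import run_ablation_on_cohort
from levoresp.selection import SelectionConfig

cfg = SyntheticConfig(n_patients=73, records_per_patient=3,
                      intensity_effect=1.5, age_slope=-0.5,
                      n_healthy=60, seed=1)
cohort = generate_cohort(cfg)
print(f"records: {len(cohort.clinical)}  good responders: {int(cohort.y.sum())}")

results, summary = run_ablation_on_cohort(
    cohort, method="gmi", models=("svm",), n_seeds=10,
    split_seed=1, selection_config=SelectionConfig(n_repeats=2),
)
print(summary.round(3).to_string(index=False))
```

prints

```
records: 219  good responders: 114
model  imaging_mean  imaging_sd  clinical_mean  clinical_sd  union_mean  union_sd  p_union_gt_clinical
  svm           1.0         0.0          0.678        0.002         1.0       0.0                  0.0
```

Reading: with a strong planted imaging effect (*d* = 1.5 in one ROI) the
imaging features separate the classes perfectly on the held-out test set
(AUC 1.0), the clinical covariates alone reach AUC ≈ 0.68 through their
weak configured class link, and adding imaging to clinical (union) is a
significant improvement (paired one-tailed p, degenerate-sd convention
p = 0 when the difference is constant and positive). On a null cohort
(`intensity_effect=0, texture_effect=1, clinical_link=0`) the same pipeline
stays at chance — see `tests/test_acceptance.py`.

The same experiment is scriptable from the shell:

```bash
levoresp simulate --config cfg.yaml
levoresp features --config cfg.yaml --method gmi
levoresp select   --config cfg.yaml --method gmi
levoresp train    --config cfg.yaml --method gmi
```

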