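# pituradiomics

An MRI radiomics pipeline for predicting **progression/recurrence (P/R)** of
non-functioning pituitary macroadenomas (NFPAs) from two preoperative MRI
contrasts: contrast-enhanced T1-weighted (CE T1WI) and T2-weighted (T2WI)
volumes. Roughly half of these benign tumors regrow after surgery; a
quantitative preoperative risk score helps plan resection extent,
radiotherapy, and follow-up intervals.

The package implements the full analysis chain as a reusable library:

1. **Synthetic phantom cohorts** — two-channel ellipsoidal tumor phantoms
   with class-dependent size and texture, clinical covariates, and censored
   progression-free-survival times, so every stage is testable without
   patient data.
2. **Segmentation** — isotropic resampling, slice-wise fuzzy c-means (FCM)
   clustering inside an operator rectangle, 3D largest-component and
   hole-fill cleanup, affine mask transfer between contrasts, ROI
   z-normalization, and boundary erosion shells (0.25 / 0.5 cm).
3. **Radiomics features** — a from-scratch 107-feature bank per modality
   (18 first-order, 14 shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM,
   14 GLDM), 214 features per case, verified against exhaustive brute-force
   enumeration and scikit-image's co-occurrence implementation.
4. **Model** — sequential forward feature selection driven by a
   Gaussian-kernel SVM under repeated stratified 10-fold cross-validation,
   and the SVM risk score

   f(x) = Σₙ wₙ yₙ G(xₙ, x) + b,  G(xₙ, x) = exp(−‖xₙ − x‖²),

   where xₙ are support vectors, yₙ ∈ {−1, +1}, wₙ ≥ 0 and b the bias,
   evaluated on standardized features.
5. **Evaluation & outcomes** — ROC analysis with Youden-optimal cutoff,
   per-ROI-variant confusion tables (TP/TN/FP/FN/accuracy/AUC), the >2 mm
   progression rule and <10 % gross-total-resection rule, chi-square /
   Fisher / Mann-Whitney group comparisons, Kaplan-Meier + log-rank
   progression-free survival, and univariate → multivariate Cox modelling
   with p < 0.05 promotion.

## Worked example

`examples/` contains one short script per capability. The full pipeline on
a 24-case synthetic cohort (`python examples/05_full_pipeline.py`) prints:

```
median segmentation Dice: 0.906

per-variant confusion (TP/TN/FP/FN, accuracy, AUC):
  original     12/11/ 0/ 1  acc 0.96  AUC 0.97  selected: t1ce_ngtdm_busyness|t1ce_glcm_maximum_probability
  eroded_025   13/11/ 0/ 0  acc 1.00  AUC 1.00  selected: t1ce_gldm_small_dependence_high_gray_level_emphasis
  eroded_05    13/10/ 1/ 0  acc 0.96  AUC 0.94  selected: t1ce_gldm_gray_level_nonuniformity|t1ce_firstorder_median

Kaplan-Meier split at SVM-score cutoff 0.658: log-rank p = 8.04e-07
```

Reading the output: the FCM segmentation overlaps the known truth masks at
Dice ≈ 0.9; each ROI variant gets its own selected feature subset and
out-of-fold confusion row; and dichotomizing cases at the ROC-optimal SVM
score cutoff separates the progression-free-survival curves (tiny log-rank
p), the behavior the score is designed to show. On synthetic cohorts the
classes are well separated by construction, so accuracies run higher than
one should expect on clinical data.

The same flow is scriptable from the shell:

```bash
pituradiomics run-all --out runs/demo --seed 1 --n-cases 50
pituradiomics simulate --n-cases 50 --seed 0 --out cohort/
pituradiomics segment --t1ce case_t1ce.nii.gz --t2 case_t2.nii.gz --out masks/
```

## Layout

```
src/pituradiomics/
  phantom.py        synthetic cohorts, survival simulation
  segmentation.py   resampling, normalization, FCM, cleanup, transfer, erosion
  features/         the 214-feature bank (one module per family)
  selection.py      CV objective, forward selection, SVM training and score
  metrics.py        ROC, Youden cutoff, confusion summaries
  outcomes.py       clinical rules, group tests, Kaplan-Meier, Cox
  pipeline.py       end-to-end orchestration with provenance hashes
  cli.py            thin click CLI (simulate/segment/features/select/score/outcome/run-all)
docs/methods.md     model and design notes
examples/           one narrative script per capability
tests/              pytest suite incl. brute-force texture oracles
```
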