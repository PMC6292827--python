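# petpattern

Metabolic brain patterns from FDG-PET, for neuroimaging researchers who
want voxelwise, classifier-derived disease patterns and per-subject
expression scores with honest cross-validated performance estimates.

Regional glucose metabolism imaged by ¹⁸F-FDG PET distinguishes
neurodegenerative diseases with overlapping clinical presentations (e.g.
amyotrophic lateral sclerosis versus Parkinson-plus syndromes). This
package derives such patterns from cohorts of spatially normalized scans:
it classifies subjects with a generalized linear model

    y = f(wᵀAx + b)

where `x` is the smoothed, masked, demeaned, L2-normalized voxel vector of
a scan, `A` a PCA feature transform (or the identity), and `(w, b)` fitted
by regularized loss minimization — a linear soft-margin SVM
(½‖w‖² + C Σ hinge) or elastic-net logistic regression
(log-loss + λ[(1−α)/2‖w‖² + α‖w‖₁]). The trained model maps back to voxel
space as the pattern `Aᵀw`, an image whose inner product with any
preprocessed scan — the *expression score* ⟨Aᵀw, x⟩ — measures how strongly
that scan expresses the disease topography. Patterns can be
*discriminative* (patient group vs patient group) or *disease-specific*
(patient group vs healthy controls); pairs of disease-specific expression
scores support a second-stage 2-D classification. Evaluation uses repeated
stratified nested cross-validation (hyperparameters tuned on inner folds
only, PCA refit per training fold), ROC/AUC, sensitivity/specificity,
Pearson correlations between classifiers' scores and patterns, and the RV
coefficient between score-pair sets.

A synthetic phantom generator produces cohorts of 3-D volumes with known
ground-truth patterns, subject-level expression variability, global
dose/scanner scaling and smoothed noise, so the entire pipeline is testable
end to end without any data download. See `docs/methods.md` for the model,
defaults, and what the phantom does and does not emulate.

## Worked example

Simulate a small two-group phantom cohort and run the direct-classification
workflow with a PCA-SVM:

```sh
petpattern simulate --out data --n-hc 0 --n-a 6 --n-b 6 --seed 3
petpattern run-direct --manifest data/manifest.tsv --mask data/mask.nii.gz \
    --classifiers pca_svm --outer-k 3 --inner-k 3 --n-repeats 1 \
    --seed 1 --out results
petpattern report results
```

which prints

```
pca_svm: AUC 1.000 ± 0.000  sens 1.000  spec 1.000
```

The 12 phantom subjects carry strong, distinct group patterns, so the
nested CV separates them perfectly: every held-out subject's decision
score has the correct sign (sensitivity and specificity 1.0 at the zero
threshold) and all positive-class scores exceed all negative-class scores
(AUC 1.0). `results/` then contains `metrics.json` (mean ± sd per metric),
`scores.csv` (per-subject repeat-averaged decision scores),
`roc_pca_svm.csv` (the pooled ROC curve), and
`pattern_direct_pca_svm.nii.gz` + `.json` — the voxelwise pattern, positive
where group A is relatively hypermetabolic. The same library calls are
available in Python (`petpattern.workflows.run_direct`), and
`run-disease-specific` adds patterns versus controls, per-subject
(s_A, s_B) expression-score pairs, RV coefficients between classifiers,
and the second-stage SVM in the score plane.

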