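# Methods

## The model

A subject's spatially normalized FDG-PET scan is reduced to a vector
`x` of in-mask voxel values. Classification between two groups uses a
generalized linear model

    y = f(w' A x + b)

with a linear feature transform `A`, feature-space weights `(w, b)`, and an
activation `f` — a step function for the support vector machine, the
logistic sigmoid for logistic regression. Because the voxel dimension
(thousands to hundreds of thousands) vastly exceeds the number of subjects,
`(w, b)` are obtained by regularized loss minimization:

    w* = argmin_w  (1/N) Σ_n L_n(w, b) + λ R(w).

Three variants are implemented:

* **svm** — linear soft-margin SVM directly on voxel vectors:
  `min ½‖w‖² + C Σ max(0, 1 − t_n(w·x_n + b))`, solved via libsvm's exact
  C-SVC dual (scikit-learn `SVC`, linear kernel). The "kernel scale"
  hyperparameter divides features before fitting.
* **pca_svm** — PCA feature transform, then the same SVM.
* **pca_lr** — PCA, then elastic-net logistic regression:
  `(1/N) Σ log(1 + exp(−t_n(w·x_n + b))) + λ[(1−α)/2‖w‖² + α‖w‖₁]`,
  intercept unpenalized, solved by scikit-learn's saga coordinate-style
  descent with the exact mapping `C = 1/(Nλ)`, `l1_ratio = α`. Because a
  penalty-dominated solve can leave the unpenalized intercept short of its
  optimum, the intercept is polished afterwards by an exact 1-D Newton
  solve given `w`.

**PCA.** Components are eigenvectors of the centered training covariance,
obtained by economy SVD of the centered `N × p` matrix (never forming the
`p × p` covariance). *All* components above the numerical-rank threshold
(eigenvalue > 1e-10 × largest) are retained; the downstream classifier
assigns each component its weight, rather than a heuristic subset-selection
rule. Consequently `k ≤ min(N−1, p)`.

**Patterns and expression scores.** A trained feature-space model maps to
voxel space as the pattern `A'w`; since
`w'A(x − m) + b = ⟨A'w, x⟩ + (b − w'Am)`, the PCA-centering shift is
absorbed into the stored intercept, and classification by the sign of the
intercept-included projection reproduces the model's predictions exactly
(verified to 1e-10 in tests). The *expression score* of a scan is the plain
projection `⟨A'w, x⟩` — by default without the intercept, which only
matters for classification, not for score comparisons. Positive pattern
weights mark relative hypermetabolism in the positive class. When a kernel
scale `s ≠ 1` was used, `w/s` is folded into the voxel weights so the
pattern remains a faithful linear functional of the raw preprocessed scan;
for `s = 1` the pattern norm equals `‖w‖` exactly.

## Preprocessing

Per subject, in this order: isotropic Gaussian smoothing (default FWHM
6 mm; per-axis sigma in voxel units = FWHM / (voxel size × 2√(2 ln 2));
reflect boundary, which preserves constants exactly) → masking and
vectorization (frozen ordering: first axis fastest, i.e. column-major) →
subtraction of the in-mask mean → division by the L2 norm. Demean + L2
makes the output *exactly* invariant to any global multiplicative intensity
factor (injected dose, scanner sensitivity); in IEEE arithmetic the
invariance is bitwise for binary scale factors and holds to machine
precision otherwise. The mean is taken over in-mask voxels only — the only
defensible choice once the scan is vectorized. An optional histogram
normalization (rank-based quantile mapping onto a reference distribution,
e.g. pooled training intensities) is available but off by default; the
default pipeline is demean + L2 alone.

## Cross-validation and tuning

Performance is estimated by stratified 10-fold outer CV repeated over
independent random fold draws (default 10 repeats); per fold class counts
deviate from the proportional split by at most one subject. Inside every
outer training set, a stratified 10-fold inner loop selects hyperparameters
by grid search maximizing mean inner AUC. AUC ties are common when the
effect is strong — much of the grid can rank every inner fold perfectly —
and selecting among tied points by regularization strength alone drifts to
the edge of the grid, where coefficients are barely nonzero and
fold-varying intercepts dominate the pooled out-of-fold scores. Ties are
therefore broken first by the smaller inner-test loss (binomial deviance
for logistic regression, hinge for the SVM), so the chosen model is well
calibrated as well as well ranked, and only then toward stronger
regularization (smaller C / larger λ). Default grids:

* SVM: `C ∈ 10^{−3..3}` (7 log-spaced) × kernel scale `∈ {1, √k, k}`
  (k = feature count).
* Elastic-net LR: `α ∈ {0.1, 0.5, 0.9}` × a 25-point log-spaced λ path from
  `λ_max` (the smallest λ zeroing all coefficients at the null model) down
  four decades. The path is fit warm-started from strong to weak
  regularization; tuning solves are iteration-capped (they only *rank* grid
  points), and the winning point is refit to full tolerance.

PCA is refit inside every training fold — outer and inner — so no test
subject ever influences a fitted transform (asserted by an instrumented
fold audit in the tests). Two computational identities keep this honest CV
affordable: the linear-kernel Gram matrix is computed once per inner fold
and reused for every (C, scale) grid point (`K/s²`); and because full-rank
PCA is an isometry on the training span, PCA-SVM tuning uses centered raw
Grams with no eigendecomposition at all — a mathematically identical
shortcut, verified against the explicit route in the acceptance tests.

Out-of-fold decision scores give one score per subject per repeat.
Reported metrics are the mean ± sd over repeats of AUC (Mann–Whitney
statistic, ties ½), sensitivity and specificity; the "average ROC curve"
pools each subject's repeat-averaged score into a single curve. The default
operating point is the sign of the decision value (a score of exactly 0
counts as negative); the equal-error point (|sens − spec| minimized, ties
toward higher sensitivity) is available because "prediction accuracy" at
the sens = spec ROC point is a standard summary for these classifiers.

**Disease-specific workflow.** An A-specific pattern is trained on
A-vs-controls, a B-specific pattern on B-vs-controls. Per repeat and outer
fold, a pattern is trained on the fold's training subjects; cohort subjects
are scored only by the pattern from the fold that held them out, while
subjects outside that cohort (e.g. B patients scored on the A pattern) are
scored by every fold's pattern and averaged — no subject is ever scored by
a pattern trained on itself. Repeat-averaged (s_A, s_B) pairs then feed a
second-stage linear SVM in the 2-D score plane (C tuned by inner CV, kernel
scale fixed at 1 — with two features, scale tuning is meaningless).
Agreement between classifiers' score-pair sets uses the RV coefficient
RV(X,Y) = tr(S_X S_Y)/√(tr(S_X²) tr(S_Y²)) on column-centered matrices
(centering is applied internally even to pre-centered input, for
idempotence); RV reduces to the squared Pearson correlation for single
columns and is invariant to rotation and rescaling of either block.

## Synthetic phantom cohorts

Every claim above is testable without any data download via the phantom
generator. A subject volume is

    V = g · (T + z · P_group + ε_smoothed)

on a default 32³ grid of 2 mm voxels with an ellipsoidal "brain" mask
(radii 26/28/24 mm, ≈ 9200 in-mask voxels): `T` is a smooth background
(amplitude 100, brighter centrally); `P_group` is the group's ground-truth
pattern — smooth spherical caps mixing hyper- and hypometabolic regions
(amplitudes 4–6 % of background, the magnitude of real FDG disease
effects), zero for controls, zero-mean over the mask; `z ~ N(1, 0.2²)`
truncated at 0 models subject-level expression variability;
`ε` is white Gaussian noise smoothed at 6 mm FWHM; and
`g ~ Uniform(0.8, 1.25)` is the global dose/scanner factor that demean + L2
provably erases. Default cohort sizes are 70/33/29 (patients A / patients
B / controls). The noise amplitude is calibrated analytically — not by
trial — so that the smoothed-noise in-mask sd equals the in-mask RMS of the
between-group pattern contrast (contrast-to-noise ratio 1), using the exact
sd gain of the smoothing kernel computed from its impulse response. An
optional multiplicative `scanner_offset` field emulates residual
inter-scanner bias. All draws are reproducible from (cohort seed, group,
subject index).

What the phantom does *not* emulate: anatomy (region positions are
geometry, not brain regions), scanner point-spread anisotropy, attenuation
or reconstruction artifacts, registration error, and age/sex covariates.
Passing recovery tests therefore demonstrates the correctness and internal
consistency of the pipeline under its stated noise model — not clinical
performance on real cohorts.

## Numerical choices and degenerate inputs

* Geometry equality tolerance: 1e-4 mm on affine entries (header
  round-trips through converters make exact equality brittle).
* SVC tolerance 1e-8 for final fits (duality-gap agreement with a generic
  QP solve to 1e-5 relative on small problems); 1e-6 in tuning.
* saga tolerance 1e-7 / 50k iterations for final LR fits; 1e-4 / 400
  warm-started iterations inside tuning.
* Constant image over the mask → explicit error naming the subject (the
  demeaned vector would be zero and cannot be L2-normalized).
* Rank-0 training matrices and single-class fits are rejected with
  explicit errors; folds whose smallest class is smaller than k trigger a
  reduction of k with a warning; k = N degenerates to singleton folds.
* Non-unit-norm input to an expression score warns rather than errors (raw
  projections remain meaningful).

## Problem sizes used by scripts/acceptance.py

The default 32³ grid keeps a full nested 10×10 CV run in minutes on one
CPU. The script runs the direct arm on the default 70/33 cohort with 10
repeats for the SVM variants and 3 for elastic-net LR (whose
regularization-path fits dominate runtime), and the disease-specific arm on
40/40 patients + 30 controls with 3 repeats using PCA-SVM — the classifier
carried into the second stage — plus a 10-repeat permutation null as a
leakage guard. These sizes are the package's own reporting choices; all of
them can be raised via `RunConfig`/`FoldScheme`.

## Known limitations

* Inputs must already be spatially normalized; no registration is
  performed or checked beyond grid-geometry equality.
* Only the pooled two-group design is supported (no multiclass, no
  subtype-specific patterns).
* The optional histogram normalization defines its reference as a supplied
  intensity sample (e.g. pooled training voxels); no canonical reference
  distribution ships with the package.
* Elastic-net logistic regression at λ → 0 on separable data has no finite
  minimizer; the solver's iteration cap then acts as implicit
  regularization, which is why the λ path stops four decades below λ_max.
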