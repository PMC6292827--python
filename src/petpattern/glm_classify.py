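"""Generalized-linear-model classification core.

The model is y = f(w' A x + b): a linear feature transform A (here PCA, or
the identity), a weight vector w and intercept b fitted by regularized loss
minimization, and an activation f (step for the SVM, logistic sigmoid for
logistic regression). Three classifier variants are supported:

* ``svm``     — linear soft-margin SVM directly on voxel vectors
* ``pca_svm`` — PCA feature transform, then linear soft-margin SVM
* ``pca_lr``  — PCA feature transform, then elastic-net logistic regression

The SVM minimizes (1/2)||w||^2 + C * sum_n max(0, 1 - t_n (w.x_n + b)).
The "kernel scale" hyperparameter of the linear kernel is realized by
dividing features by the scale before fitting.

The elastic-net logistic regression minimizes
(1/N) sum_n log(1 + exp(-t_n (w.x_n + b)))
+ lambda * [ (1 - alpha)/2 ||w||^2 + alpha ||w||_1 ],
with an unpenalized intercept; alpha in [0, 1] mixes ridge and lasso.

PCA retains every component above the numerical-rank threshold; weights for
all components are assigned by the downstream classifier rather than by a
heuristic component-selection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

RANK_TOL = 1e-10  # eigenvalue threshold relative to the largest


# ---------------------------------------------------------------------------
# data containers

@dataclass
class PCAModel:
    """Training mean plus orthonormal principal components (the transform A)."""

    mean: np.ndarray          # (p,)
    components: np.ndarray    # (k, p), orthonormal rows
    eigenvalues: np.ndarray   # (k,), nonincreasing

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def p(self) -> int:
        return self.components.shape[1]


@dataclass
class LinearModel:
    """Feature-space weights (w, b) with the loss spec that produced them."""

    w: np.ndarray
    b: float
    loss_spec: str                      # "hinge_l2" | "logistic_elasticnet"
    hyperparams: dict = field(default_factory=dict)
    label_map: dict = field(default_factory=lambda: {"positive": 1, "negative": -1})

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.b = float(self.b)
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.b):
            raise ValueError("non-finite model coefficients")


@dataclass
class LabeledFeatures:
    """N x k feature matrix with labels in {-1, +1}."""

    X: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.t = np.asarray(self.t, dtype=int).ravel()
        if self.X.shape[0] != self.t.size:
            raise ValueError("X and t disagree on N")
        if not set(np.unique(self.t)) <= {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")
        if len(np.unique(self.t)) < 2:
            raise ValueError("both classes must be present")


# ---------------------------------------------------------------------------
# PCA feature transform

def fit_pca(X: np.ndarray) -> PCAModel:
    """PCA of the row-observations matrix X (N subjects x p voxels).

    Components are the eigenvectors of the centered data covariance with
    eigenvalue above ``max(eigenvalue) * 1e-10``; all such components are
    retained (k <= min(N-1, p)). Computed by economy SVD of the centered
    matrix, which gives the covariance eigenpairs without ever forming the
    p x p covariance — the standard route when p >> N.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 subjects")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD: Xc = U S Vt; covariance eigenvalues = S^2/(N-1), eigenvectors = rows of Vt
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    if eig.size == 0 or eig[0] <= 0:
        raise ValueError("rank-0 data: all rows identical")
    keep = eig > eig[0] * RANK_TOL
    return PCAModel(mean=mean, components=vt[keep], eigenvalues=eig[keep])


def pca_transform(model: PCAModel, x: np.ndarray) -> np.ndarray:
    """Project one vector or an N x p matrix: components . (x - mean)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.p:
        raise ValueError(f"dimension mismatch: {x.shape[-1]} != p = {model.p}")
    return (x - model.mean) @ model.components.T


# ---------------------------------------------------------------------------
# classifiers

def fit_linear_svm(data: LabeledFeatures, C: float, scale: float = 1.0) -> LinearModel:
    """Linear soft-margin SVM: min (1/2)||w||^2 + C sum hinge.

    Features are divided by ``scale`` before fitting; the returned (w, b)
    operate on the *scaled* features (callers scale consistently at predict
    time via :func:`decision_value` with the stored hyperparams).
    """
    if C <= 0 or scale <= 0:
        raise ValueError("C and scale must be positive")
    Xs = data.X / scale
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(Xs, data.t)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    # sklearn orients the decision toward classes_[1]; with labels {-1,+1}
    # classes_[1] == +1 so no sign flip is needed, but guard regardless.
    if clf.classes_[1] == -1:
        w, b = -w, -b
    return LinearModel(w=w, b=b, loss_spec="hinge_l2",
                       hyperparams={"C": float(C), "scale": float(scale)})


def svm_primal_objective(model: LinearModel, data: LabeledFeatures) -> float:
    """(1/2)||w||^2 + C sum hinge on the (scaled) training data."""
    C = model.hyperparams["C"]
    scale = model.hyperparams.get("scale", 1.0)
    margins = data.t * ((data.X / scale) @ model.w + model.b)
    return 0.5 * float(model.w @ model.w) + C * float(np.maximum(0.0, 1.0 - margins).sum())


def fit_logistic_elasticnet(data: LabeledFeatures, alpha: float, lam: float) -> LinearModel:
    """Elastic-net logistic regression by coordinate-style descent.

    Minimizes (1/N) sum log(1+exp(-t(w.x+b))) + lam*[(1-alpha)/2 ||w||^2
    + alpha ||w||_1], intercept unpenalized. ``lam = 0`` gives the
    unpenalized maximum-likelihood fit.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n = data.X.shape[0]
    if lam == 0.0:
        clf = LogisticRegression(penalty=None, solver="lbfgs", tol=1e-10, max_iter=10_000)
    else:
        # sklearn objective: C * sum(logloss) + l1_ratio*||w||_1 + (1-l1_ratio)/2*||w||^2
        # dividing ours by lam maps C = 1/(N*lam), l1_ratio = alpha.
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", C=1.0 / (n * lam),
            l1_ratio=alpha, tol=1e-7, max_iter=50_000,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(data.X, data.t)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    if clf.classes_[1] == -1:
        w, b = -w, -b
    # the intercept is unpenalized: polish it with an exact 1D Newton solve
    # given w (the solver's stopping rule can leave b under-converged when
    # the penalty dominates)
    b = _newton_intercept(data.X, data.t, w, b)
    return LinearModel(w=w, b=b, loss_spec="logistic_elasticnet",
                       hyperparams={"alpha": float(alpha), "lambda": float(lam)})


def _newton_intercept(X, t, w, b0: float) -> float:
    """Minimize mean logistic loss over the intercept alone (1D, convex)."""
    from scipy.special import expit

    z0 = X @ w
    b = b0
    for _ in range(50):
        p = expit(z0 + b)          # P(t = +1 | x)
        y = (t > 0).astype(float)
        g = float(np.mean(p - y))
        h = float(np.mean(p * (1.0 - p)))
        if h < 1e-12 or abs(g) < 1e-12:
            break
        b -= g / h
    return float(b)


def lambda_max(X: np.ndarray, t: np.ndarray, alpha: float) -> float:
    """Smallest lambda (at given alpha > 0) for which the lasso part zeroes w.

    From the null model (intercept only): lam_max = max_j |(1/N) sum_n
    x_nj (y_n - p_bar)| / alpha with y in {0,1} and p_bar the base rate.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t).ravel()
    y = (t > 0).astype(float)
    grad = X.T @ (y - y.mean()) / X.shape[0]
    lmax = float(np.abs(grad).max())
    return lmax / max(alpha, 1e-3)


def lambda_path(X, t, alpha, n_points: int = 25, decades: float = 4.0) -> np.ndarray:
    """Log-spaced lambda path from lambda_max down ``decades`` decades."""
    lmax = lambda_max(X, t, alpha)
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_points)


def decision_value(model: LinearModel, x_feat: np.ndarray) -> np.ndarray | float:
    """w . x + b for one feature vector or an N x k matrix.

    Classification is the sign of this value for the SVM; the logistic
    sigmoid of it gives the class probability for logistic regression.
    SVM kernel scale stored in the model is applied to the input.
    """
    x = np.asarray(x_feat, dtype=float)
    if x.shape[-1] != model.w.size:
        raise ValueError(f"dimension mismatch: {x.shape[-1]} != {model.w.size}")
    scale = model.hyperparams.get("scale", 1.0)
    out = (x / scale) @ model.w + model.b
    return float(out) if np.ndim(out) == 0 else out


def predict_proba(model: LinearModel, x_feat: np.ndarray):
    """Logistic-sigmoid probability of the positive class."""
    from scipy.special import expit

    return expit(decision_value(model, x_feat))


# ---------------------------------------------------------------------------
# hyperparameter tuning (inner CV loop)

def default_svm_grid(n_features: int) -> list[dict]:
    """C on 7 log-spaced points 1e-3..1e3, kernel scale in {1, sqrt(k), k}."""
    Cs = np.logspace(-3, 3, 7)
    scales = [1.0, float(np.sqrt(n_features)), float(n_features)]
    # order: stronger regularization first (small C, large scale) so that
    # ties break toward it
    return [{"C": float(C), "scale": s} for C in Cs for s in sorted(set(scales), reverse=True)]


def default_lr_grid(X, t, alphas=(0.1, 0.5, 0.9), n_lambda: int = 25) -> list[dict]:
    """alpha x lambda grid; lambda path from lambda_max down 4 decades."""
    grid = []
    for a in alphas:
        for lam in lambda_path(X, t, a, n_points=n_lambda):
            grid.append({"alpha": float(a), "lambda": float(lam)})
    # stronger regularization (larger lambda) first for tie-breaking
    grid.sort(key=lambda g: (-g["lambda"], g["alpha"]))
    return grid


def _fit_for(spec_method: str, data: LabeledFeatures, params: dict) -> LinearModel:
    if spec_method in ("svm", "pca_svm"):
        return fit_linear_svm(data, C=params["C"], scale=params.get("scale", 1.0))
    if spec_method == "pca_lr":
        return fit_logistic_elasticnet(data, alpha=params["alpha"], lam=params["lambda"])
    raise ValueError(f"unknown classifier method: {spec_method}")


def _lr_path_aucs(Xtr, ttr, Xte, tte, grid) -> tuple[np.ndarray, np.ndarray]:
    """Inner-fold AUC and binomial deviance for every (alpha, lambda) grid
    point, warm-starting the solver along each descending lambda path."""
    from sklearn.metrics import roc_auc_score

    aucs = np.zeros(len(grid))
    losses = np.zeros(len(grid))
    by_alpha: dict[float, list[int]] = {}
    for gi, g in enumerate(grid):
        by_alpha.setdefault(g["alpha"], []).append(gi)
    n = Xtr.shape[0]
    for alpha, idxs in by_alpha.items():
        idxs = sorted(idxs, key=lambda i: -grid[i]["lambda"])  # strong -> weak
        # tuning only ranks grid points; a capped, warm-started solve is
        # plenty for ranking and keeps the path fit fast. The winning point
        # is refit to full tolerance afterwards.
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=alpha,
            tol=1e-4, max_iter=400, warm_start=True, C=1.0,
        )
        for gi in idxs:
            lam = grid[gi]["lambda"]
            clf.C = 1.0 / (n * lam) if lam > 0 else 1e12
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xtr, ttr)
            s = Xte @ clf.coef_.ravel() + clf.intercept_[0]
            if clf.classes_[1] == -1:
                s = -s
            aucs[gi] += roc_auc_score(tte, s)
            losses[gi] += float(np.mean(np.logaddexp(0.0, -tte * s)))
    return aucs, losses


def tune_hyperparameters(
    data: LabeledFeatures,
    method: str,
    grid: list[dict],
    inner_k: int = 10,
    seed: int = 0,
    use_pca: bool | None = None,
) -> dict:
    """Pick the grid point maximizing mean inner-CV AUC.

    AUC ties — common when the effect is strong enough that much of the
    grid ranks the inner folds perfectly — are broken by the smaller
    inner-test loss (binomial deviance for LR, hinge for SVM), so the
    selected model is also well calibrated, not merely well ranked;
    remaining ties fall back to grid order, and the default grids list
    stronger regularization first (smaller C / larger lambda). Folds are
    stratified; if a class has fewer members than ``inner_k`` the fold
    count is reduced. When the method uses PCA, the transform is refit on
    each inner training fold and applied to the held-out fold — no
    inner-test subject ever touches a fitted transform.
    """
    from sklearn.metrics import roc_auc_score

    if inner_k < 2:
        raise ValueError("inner_k must be >= 2")
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if use_pca is None:
        use_pca = method in ("pca_svm", "pca_lr")
    counts = np.bincount((data.t > 0).astype(int), minlength=2)
    k = min(inner_k, int(counts.min()))
    if k < 2:
        raise ValueError("a class has < 2 members; cannot build stratified inner folds")
    if k < inner_k:
        warnings.warn(f"reducing inner folds from {inner_k} to {k} (small class)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = np.zeros(len(grid))
    losses = np.zeros(len(grid))
    for train_idx, test_idx in skf.split(data.X, data.t):
        Xtr, ttr = data.X[train_idx], data.t[train_idx]
        Xte, tte = data.X[test_idx], data.t[test_idx]
        if len(np.unique(tte)) < 2:  # cannot score AUC on one class
            continue
        if use_pca:
            if method == "pca_svm":
                # full-rank PCA is an isometry on the training span, and the
                # SVM solution lives in that span: centering alone gives the
                # identical linear-kernel Gram, so no eigendecomposition is
                # needed inside the tuning loop.
                mu = Xtr.mean(axis=0)
                Xtr = Xtr - mu
                Xte = Xte - mu
            else:
                pca = fit_pca(Xtr)
                Xtr = pca_transform(pca, Xtr)
                Xte = pca_transform(pca, Xte)
        if method == "pca_lr":
            a, l = _lr_path_aucs(Xtr, ttr, Xte, tte, grid)
            aucs += a
            losses += l
        else:
            # linear kernel: K/s^2 is the Gram of x/s, so one Gram per fold
            # serves every (C, scale) grid point
            G_tr = Xtr @ Xtr.T
            G_te = Xte @ Xtr.T
            for gi, params in enumerate(grid):
                s2 = params.get("scale", 1.0) ** 2
                clf = SVC(kernel="precomputed", C=params["C"], tol=1e-6)
                clf.fit(G_tr / s2, ttr)
                scores = clf.decision_function(G_te / s2)
                if clf.classes_[1] == -1:
                    scores = -scores
                aucs[gi] += roc_auc_score(tte, scores)
                losses[gi] += float(np.mean(np.maximum(0.0, 1.0 - tte * scores)))
    # lexicographic: max AUC, then min inner-test loss, then grid order
    order = np.lexsort((np.arange(len(grid)), losses, -aucs))
    return dict(grid[int(order[0])])


# ---------------------------------------------------------------------------
# classifier spec

@dataclass
class ClassifierSpec:
    """Which classifier to run and with what tuning grid.

    ``grid`` of None means the default grid for the method; for pca_lr the
    default grid is data-dependent (lambda path from lambda_max) and is
    built per training set.
    """

    method: str  # "svm" | "pca_svm" | "pca_lr"
    grid: Optional[list[dict]] = None
    inner_k: int = 10

    def __post_init__(self):
        if self.method not in ("svm", "pca_svm", "pca_lr"):
            raise ValueError(f"unknown classifier method: {self.method}")

    @property
    def uses_pca(self) -> bool:
        return self.method in ("pca_svm", "pca_lr")

    def build_grid(self, X: np.ndarray, t: np.ndarray) -> list[dict]:
        if self.grid is not None:
            return self.grid
        if self.method == "pca_lr":
            return default_lr_grid(X, t)
        return default_svm_grid(X.shape[1])
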