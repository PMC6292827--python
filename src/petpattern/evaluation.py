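"""Nested cross-validation and performance metrics.

The evaluation scheme: a stratified k-fold outer loop estimates out-of-fold
decision scores; inside every outer training set, a stratified k-fold inner
loop selects classifier hyperparameters by grid search on mean AUC. The
whole scheme is repeated over several random fold draws, so every subject
accumulates one out-of-fold score per repeat, and performance is reported
as mean +/- sd over repeats. All transforms (PCA) and models are fit on
training folds only.

Metrics: ROC/AUC (Mann-Whitney statistic, ties counted 1/2), sensitivity
and specificity at the zero-decision threshold or at the equal-error ROC
point, Pearson correlation, and the RV coefficient — a multivariate
generalization of the squared Pearson correlation between two
column-centered matrices, RV(X, Y) = tr(XX'YY') / sqrt(tr((XX')^2)
tr((YY')^2)), in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .glm_classify import (
    ClassifierSpec,
    LabeledFeatures,
    PCAModel,
    _fit_for,
    decision_value,
    fit_pca,
    pca_transform,
    tune_hyperparameters,
)


# ---------------------------------------------------------------------------
# fold schemes

@dataclass
class FoldScheme:
    """Stratified fold assignments for repeated k-fold CV."""

    outer_k: int = 10
    inner_k: int = 10
    n_repeats: int = 10
    seed: int = 0
    assignments: list[np.ndarray] = field(default_factory=list)  # per repeat: subject -> fold

    def materialize(self, labels) -> "FoldScheme":
        labels = np.asarray(labels).ravel()
        self.assignments = [
            make_folds(labels, self.outer_k, seed=self.seed + 1000 * r)
            for r in range(self.n_repeats)
        ]
        return self


def make_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Stratified random partition into k folds; returns subject -> fold.

    Per fold, each class count differs from the ideal proportional split by
    at most 1 (balance in group sizes is preserved across folds). If the
    smaller class has fewer than k members, k is reduced with a warning.
    """
    labels = np.asarray(labels).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k == labels.size:  # leave-one-out degenerate case: singleton folds
        return np.random.default_rng(seed).permutation(labels.size)
    _, counts = np.unique(labels, return_counts=True)
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        warnings.warn(f"reducing folds from {k} to {k_eff} (smallest class)")
    if k_eff < 2:
        raise ValueError("smallest class has < 2 members")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# result container

@dataclass
class CVResult:
    """Out-of-fold scores and summary metrics from repeated nested CV."""

    scores: np.ndarray                 # N x n_repeats out-of-fold decision scores
    labels: np.ndarray                 # length N, in {-1, +1}
    fold_assignments: list[np.ndarray]
    chosen_params: list[list[dict]]    # [repeat][fold] -> hyperparams
    per_repeat: pd.DataFrame           # columns auc, sensitivity, specificity

    @property
    def mean_scores(self) -> np.ndarray:
        """Per-subject score averaged over repeats."""
        return self.scores.mean(axis=1)

    @property
    def summary(self) -> dict:
        out = {}
        for m in ("auc", "sensitivity", "specificity"):
            out[m] = float(self.per_repeat[m].mean())
            out[f"{m}_sd"] = float(self.per_repeat[m].std(ddof=1)) if len(self.per_repeat) > 1 else 0.0
        return out

    def pooled_roc(self):
        """One ROC over repeat-averaged scores (the 'average ROC curve')."""
        return roc_auc(self.mean_scores, self.labels)


# ---------------------------------------------------------------------------
# metrics

def roc_auc(scores, labels):
    """ROC curve (all thresholds) and AUC as the Mann-Whitney statistic.

    Returns ``(curve, auc)`` where curve is a DataFrame with columns
    threshold, sensitivity, specificity. Ties count 1/2 toward the AUC.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, scores, pos_label=np.max(labels),
                              drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    curve = pd.DataFrame({"threshold": thr, "sensitivity": tpr, "specificity": 1 - fpr})
    return curve, auc


def sens_spec(scores, labels, mode: str = "zero_threshold") -> tuple[float, float]:
    """Sensitivity and specificity of sign-of-decision or equal-error point.

    ``zero_threshold``: predict positive iff score > 0 (the classifier's own
    operating point). ``equal_error``: the ROC point minimizing |sens -
    spec|, ties resolved toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels == np.max(labels)
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    if mode == "zero_threshold":
        pred = scores > 0
        sens = float((pred & pos).sum() / pos.sum())
        spec = float((~pred & ~pos).sum() / (~pos).sum())
        return sens, spec
    if mode == "equal_error":
        curve, _ = roc_auc(scores, labels)
        gap = np.abs(curve.sensitivity.values - curve.specificity.values)
        best = np.flatnonzero(gap == gap.min())
        # ties toward higher sensitivity
        i = best[np.argmax(curve.sensitivity.values[best])]
        return float(curve.sensitivity.values[i]), float(curve.specificity.values[i])
    raise ValueError(f"unknown mode: {mode}")


def pearson(u, v) -> float:
    """Product-moment correlation coefficient."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size or u.size < 3:
        raise ValueError("pearson needs equal lengths >= 3")
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(u, v).statistic)


def rv_coefficient(X, Y) -> float:
    """RV coefficient between two subject-aligned matrices (N x p, N x q).

    Columns are centered internally; RV = tr(Sx Sy) / sqrt(tr(Sx^2)
    tr(Sy^2)) with Sx = Xc Xc', Sy = Yc Yc'. Equals the squared Pearson
    correlation when p = q = 1; invariant to orthogonal rotation and
    nonzero rescaling of either block.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1:
        X = X.T
    if Y.ndim == 2 and Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0] or X.shape[0] < 3:
        raise ValueError("RV needs the same N >= 3 in both matrices")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sx = Xc @ Xc.T
    Sy = Yc @ Yc.T
    denom = np.sqrt(np.sum(Sx * Sx) * np.sum(Sy * Sy))
    if denom == 0:
        raise ValueError("zero matrix after centering")
    return float(np.sum(Sx * Sy) / denom)


# ---------------------------------------------------------------------------
# nested cross-validation

def nested_cv(
    features: np.ndarray,
    labels,
    spec: ClassifierSpec,
    scheme: FoldScheme,
    sens_spec_mode: str = "zero_threshold",
    audit: list | None = None,
) -> CVResult:
    """Repeated stratified nested CV of one classifier spec.

    For each repeat and outer fold: build the tuning grid from the outer
    training set, select hyperparameters by inner CV (PCA refit per inner
    fold when applicable), refit transform + model on the full outer
    training set, and score the held-out fold. ``audit``, if given, receives
    (repeat, fold, train_indices, test_indices) tuples for leakage checks.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.asarray(labels, dtype=int).ravel()
    if X.shape[0] != t.size:
        raise ValueError("features and labels disagree on N")
    if not scheme.assignments:
        scheme.materialize(t)
    n = t.size
    scores = np.full((n, scheme.n_repeats), np.nan)
    chosen: list[list[dict]] = []
    rows = []
    for r, assignment in enumerate(scheme.assignments):
        chosen_r: list[dict] = []
        for fold in range(assignment.max() + 1):
            test_idx = np.flatnonzero(assignment == fold)
            train_idx = np.flatnonzero(assignment != fold)
            if audit is not None:
                audit.append((r, fold, train_idx.copy(), test_idx.copy()))
            Xtr_raw, ttr = X[train_idx], t[train_idx]
            grid_X = Xtr_raw
            pca: PCAModel | None = None
            if spec.uses_pca:
                pca = fit_pca(Xtr_raw)
                grid_X = pca_transform(pca, Xtr_raw)
            grid = spec.build_grid(grid_X, ttr)
            params = tune_hyperparameters(
                LabeledFeatures(Xtr_raw, ttr), spec.method, grid,
                inner_k=scheme.inner_k, seed=scheme.seed + 7919 * r + fold,
            )
            chosen_r.append(params)
            Xtr = grid_X  # PCA already applied if applicable
            model = _fit_for(spec.method, LabeledFeatures(Xtr, ttr), params)
            Xte = X[test_idx] if pca is None else pca_transform(pca, X[test_idx])
            scores[test_idx, r] = decision_value(model, Xte)
        chosen.append(chosen_r)
        _, auc = roc_auc(scores[:, r], t)
        se, sp = sens_spec(scores[:, r], t, mode=sens_spec_mode)
        rows.append({"repeat": r, "auc": auc, "sensitivity": se, "specificity": sp})
    assert not np.isnan(scores).any(), "every subject must get one score per repeat"
    return CVResult(
        scores=scores, labels=t, fold_assignments=list(scheme.assignments),
        chosen_params=chosen, per_repeat=pd.DataFrame(rows),
    )
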