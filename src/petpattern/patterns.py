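"""Voxel-space metabolic brain patterns and expression scores.

A trained feature-space model (w, b) with feature transform A maps back to
voxel space as the pattern A' w: the decision value w'A(x - mean) + b equals
<A'w, x> + (b - w'A mean), so the pattern plus an adjusted intercept carries
the full classifier. The projection <A'w, x> of a preprocessed scan onto the
pattern is its *expression score* — how strongly the scan expresses the
disease-related metabolic topography. Positive pattern weights mark voxels
relatively hypermetabolic in the positive class, negative weights
hypometabolic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .glm_classify import LabeledFeatures, LinearModel, PCAModel, fit_linear_svm
from .volume_io import BrainMask, MaskedVector, save_volume, load_volume, unvectorize, vectorize


@dataclass
class Pattern:
    """A voxel-space weight image with its intercept and provenance."""

    weights: MaskedVector
    intercept: float
    kind: str = "discriminative"  # or "disease_specific"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("discriminative", "disease_specific"):
            raise ValueError(f"unknown pattern kind: {self.kind}")


@dataclass
class ScorePair:
    """Per-subject expression scores on two disease-specific patterns."""

    subject_id: str
    s_A: float
    s_B: float
    n_repeats_averaged: int = 1

    def __post_init__(self):
        if not (np.isfinite(self.s_A) and np.isfinite(self.s_B)):
            raise ValueError("scores must be finite")
        if self.n_repeats_averaged < 1:
            raise ValueError("n_repeats_averaged must be >= 1")


def extract_pattern(
    pca: PCAModel | None,
    model: LinearModel,
    mask_id: str,
    kind: str = "discriminative",
    provenance: dict | None = None,
) -> Pattern:
    """Map a feature-space model to voxel space: weights = A' w.

    With ``pca=None`` (raw-space SVM) the identity transform applies and the
    weights are w itself. The PCA centering shift w'A·mean is absorbed into
    the stored intercept so that ``expression_score(..., include_intercept=
    True)`` reproduces the model's decision values exactly. The SVM kernel
    scale, if any, is folded into the weights (w/scale) for the same reason.
    """
    scale = model.hyperparams.get("scale", 1.0)
    w_eff = model.w / scale
    if pca is None:
        weights = w_eff.copy()
        intercept = model.b
    else:
        if model.w.size != pca.k:
            raise ValueError(f"dimension mismatch: w has {model.w.size}, PCA has k={pca.k}")
        weights = pca.components.T @ w_eff
        intercept = model.b - float(w_eff @ (pca.components @ pca.mean))
    return Pattern(
        weights=MaskedVector(mask_id=mask_id, values=weights),
        intercept=float(intercept),
        kind=kind,
        provenance=provenance or {"loss_spec": model.loss_spec, "hyperparams": model.hyperparams},
    )


def expression_score(
    pattern: Pattern, x: MaskedVector, include_intercept: bool = False
) -> float:
    """Project a preprocessed scan onto the pattern: <A'w, x> (+ b).

    ``x`` should be preprocessed (zero mean, unit norm); a norm deviating
    from 1 by more than 1e-6 triggers a warning, not an error, since raw
    projections can still be meaningful.
    """
    if x.mask_id != pattern.weights.mask_id:
        raise ValueError("scan and pattern are bound to different masks")
    norm = np.linalg.norm(x.values)
    if abs(norm - 1.0) > 1e-6:
        warnings.warn(
            f"input vector norm {norm:.4g} deviates from 1; was it preprocessed?"
        )
    s = float(pattern.weights.values @ x.values)
    return s + pattern.intercept if include_intercept else s


def expression_scores(pattern: Pattern, X: np.ndarray, include_intercept: bool = False):
    """Vectorized projection of an N x n_in matrix of preprocessed scans."""
    s = np.asarray(X, dtype=float) @ pattern.weights.values
    return s + pattern.intercept if include_intercept else s


def fit_score_classifier(pairs: list[ScorePair], labels, C: float = 1.0) -> LinearModel:
    """Second-stage linear SVM in the 2D (s_A, s_B) score plane.

    The decision boundary is a line, reportable as slope/intercept for
    score-plane plots. No kernel-scale tuning: two features make it moot.
    """
    X = np.array([[p.s_A, p.s_B] for p in pairs], dtype=float)
    t = np.asarray(labels, dtype=int).ravel()
    data = LabeledFeatures(X, t)  # validates both classes present
    return fit_linear_svm(data, C=C, scale=1.0)


def decision_line(model: LinearModel) -> tuple[float, float]:
    """(slope, intercept) of the 2-feature SVM boundary in the score plane."""
    w = model.w
    if w.size != 2:
        raise ValueError("decision_line requires a 2-feature model")
    if w[1] == 0:
        raise ZeroDivisionError("vertical decision boundary")
    return -w[0] / w[1], -model.b / w[1]


# ---------------------------------------------------------------------------
# persistence: NIfTI weight image + JSON sidecar

def save_pattern(pattern: Pattern, mask: BrainMask, path) -> None:
    """Write the pattern as NIfTI (out-of-mask voxels 0) + JSON sidecar."""
    path = Path(path)
    vol = unvectorize(pattern.weights, mask, fill=0.0)
    save_volume(vol, mask.geometry, path)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "intercept": pattern.intercept,
        "kind": pattern.kind,
        "mask_id": pattern.weights.mask_id,
        "provenance": pattern.provenance,
    }, indent=2))


def load_pattern(path, mask: BrainMask) -> Pattern:
    """Inverse of :func:`save_pattern`; errors if the sidecar is missing or
    the mask does not match the one the pattern was saved against."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"pattern sidecar not found: expected {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta["mask_id"] != mask.mask_id:
        raise ValueError(
            f"mask mismatch: pattern was saved for mask {meta['mask_id']}, "
            f"got {mask.mask_id}"
        )
    vol, geom = load_volume(path)
    if not geom.compatible_with(mask.geometry):
        raise ValueError("pattern geometry incompatible with mask")
    weights = vectorize(vol, mask)
    return Pattern(weights=weights, intercept=float(meta["intercept"]),
                   kind=meta["kind"], provenance=meta.get("provenance", {}))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")
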