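"""Subject-level intensity preprocessing.

The pipeline applied to every scan before classification:

    smooth (isotropic Gaussian, default FWHM 6 mm)
    -> mask & vectorize
    -> demean (subtract the in-mask mean)
    -> divide by the L2 norm

Demean followed by L2 normalization makes the subject vector exactly
invariant to any global multiplicative intensity factor (injected dose,
scanner sensitivity), which is the intended correction for inter-subject
and inter-scanner global variability.

An optional histogram normalization (quantile mapping of the in-mask
intensities onto a reference distribution) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import BrainMask, MaskedVector, VolumeGeometry, vectorize

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PreprocessConfig:
    fwhm_mm: float = 6.0
    boundary_mode: str = "reflect"
    histogram_norm: bool = False

    def __post_init__(self):
        if not np.isfinite(self.fwhm_mm) or self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be finite and >= 0")
        if self.boundary_mode != "reflect":
            raise ValueError("only 'reflect' boundary mode is supported")


def smooth(volume: np.ndarray, geometry: VolumeGeometry, fwhm_mm: float) -> np.ndarray:
    """Convolve with a normalized isotropic Gaussian of the given FWHM (mm).

    Anisotropic voxels are handled by a per-axis sigma in voxel units.
    Reflect boundary preserves constant volumes exactly; ``fwhm_mm = 0``
    returns the input unchanged.
    """
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return volume.copy()
    vs = geometry.voxel_size
    if any(v <= 0 for v in vs):
        raise ValueError("non-positive voxel size")
    sigma_vox = [fwhm_mm / (v * FWHM_PER_SIGMA) for v in vs]
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="reflect")


def demean(vec: MaskedVector) -> MaskedVector:
    """Subtract the mean over in-mask voxels."""
    if len(vec) < 2:
        raise ValueError("demean requires at least 2 in-mask voxels")
    return MaskedVector(mask_id=vec.mask_id, values=vec.values - vec.values.mean())


def l2_normalize(vec: MaskedVector, subject_id: str | None = None) -> MaskedVector:
    """Divide by the Euclidean norm; errors on an all-zero vector."""
    norm = float(np.linalg.norm(vec.values))
    if norm == 0.0:
        who = f" (subject {subject_id})" if subject_id else ""
        raise ValueError(
            f"cannot L2-normalize an all-zero vector{who}; "
            "the image is constant over the mask"
        )
    return MaskedVector(mask_id=vec.mask_id, values=vec.values / norm)


def histogram_normalize(vec: MaskedVector, reference: np.ndarray) -> MaskedVector:
    """Quantile-map in-mask intensities onto a reference distribution.

    The subject's empirical CDF is matched to that of ``reference`` (e.g. the
    pooled training-set intensities) by rank interpolation. Optional step;
    the default pipeline uses demean + L2 only.
    """
    ref = np.sort(np.asarray(reference, dtype=float).ravel())
    order = np.argsort(vec.values, kind="stable")
    ranks = np.empty(len(vec), dtype=float)
    ranks[order] = np.arange(len(vec))
    q = ranks / max(len(vec) - 1, 1)
    mapped = np.interp(q * (ref.size - 1), np.arange(ref.size), ref)
    return MaskedVector(mask_id=vec.mask_id, values=mapped)


def preprocess_subject(
    volume: np.ndarray,
    geometry: VolumeGeometry,
    mask: BrainMask,
    config: PreprocessConfig | None = None,
    subject_id: str | None = None,
    reference: np.ndarray | None = None,
) -> MaskedVector:
    """Full subject pipeline: smooth -> vectorize -> (hist) -> demean -> L2.

    Returns the unit-norm, zero-mean vector x consumed by all classifiers.
    """
    config = config or PreprocessConfig()
    sm = smooth(volume, geometry, config.fwhm_mm)
    vec = vectorize(sm, mask, geometry)
    if config.histogram_norm:
        if reference is None:
            raise ValueError("histogram_norm requires a reference distribution")
        vec = histogram_normalize(vec, reference)
    vec = demean(vec)
    return l2_normalize(vec, subject_id=subject_id)


def preprocess_cohort(volumes, geometry, mask, config=None, subject_ids=None) -> np.ndarray:
    """Preprocess a list of volumes into an N x n_in feature matrix."""
    config = config or PreprocessConfig()
    ids = subject_ids or [str(i) for i in range(len(volumes))]
    rows = [
        preprocess_subject(v, geometry, mask, config, subject_id=sid).values
        for v, sid in zip(volumes, ids)
    ]
    return np.vstack(rows)
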