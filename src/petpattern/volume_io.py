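"""NIfTI volume I/O and mask-based vectorization.

Volumes are spatially pre-normalized 3D brain images (one per subject) on a
common grid. A binary brain mask on the same grid defines which voxels enter
the analysis; every subject is represented downstream as a 1D vector of
in-mask voxel values in a fixed ordering, so that patterns computed in
different runs are directly comparable.

Vectorization ordering (frozen): ascending linear index with the first axis
fastest, i.e. Fortran/column-major order over (i, j, k).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: absolute tolerance (mm) for affine equality between geometries
AFFINE_ATOL = 1e-4


class GeometryError(ValueError):
    """Raised when volume/mask geometries are incompatible."""


@dataclass(frozen=True)
class VolumeGeometry:
    """A 3D voxel grid with its voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if any(s < 1 for s in shape) or len(shape) != 3:
            raise ValueError("shape entries must be >= 1 and 3D")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine.setflags(write=False)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm, from the affine column norms."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    def compatible_with(self, other: "VolumeGeometry") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL, rtol=0.0
        )


@dataclass(frozen=True)
class BrainMask:
    """Boolean in-brain mask bound to a grid geometry."""

    geometry: VolumeGeometry
    voxels: np.ndarray  # boolean 3D

    def __post_init__(self):
        voxels = np.asarray(self.voxels, dtype=bool)
        if voxels.shape != self.geometry.shape:
            raise GeometryError("mask shape does not match geometry")
        if not voxels.any():
            raise ValueError("mask has no in-brain voxels (n_in = 0)")
        voxels.setflags(write=False)
        object.__setattr__(self, "voxels", voxels)

    @property
    def n_in(self) -> int:
        return int(self.voxels.sum())

    @property
    def mask_id(self) -> str:
        """Short content hash binding vectors/patterns to this mask."""
        h = hashlib.sha1()
        h.update(np.asarray(self.voxels, dtype=np.uint8).tobytes())
        h.update(np.round(self.geometry.affine, 6).tobytes())
        return h.hexdigest()[:12]

    def _flat_index(self) -> np.ndarray:
        # column-major flat boolean index (first axis fastest)
        return self.voxels.reshape(-1, order="F")


@dataclass
class MaskedVector:
    """In-mask voxel values for one subject, in the frozen ordering."""

    mask_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size


def load_volume(path) -> tuple[np.ndarray, VolumeGeometry]:
    """Load a 3D NIfTI-1 volume.

    Values are returned with the format's stored scale/intercept applied and
    no further rescaling. Trailing singleton dimensions are squeezed; a true
    4D image (last dimension > 1) is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"unreadable or unsupported image: {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(dtype=np.float64))
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has shape {data.shape}")
    geom = VolumeGeometry(shape=data.shape, affine=np.asarray(img.affine))
    return data, geom


def save_volume(volume: np.ndarray, geometry: VolumeGeometry, path) -> None:
    """Write a 3D array as NIfTI-1 (.nii or .nii.gz by extension)."""
    volume = np.asarray(volume)
    if volume.shape != geometry.shape:
        raise GeometryError("volume shape does not match geometry")
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), np.asarray(geometry.affine))
    nib.save(img, str(path))


def load_mask(path, threshold: float = 0.5) -> BrainMask:
    """Load any volume as a mask; voxels are in-mask iff value > threshold."""
    data, geom = load_volume(path)
    return BrainMask(geometry=geom, voxels=data > threshold)


def vectorize(volume: np.ndarray, mask: BrainMask,
              geometry: VolumeGeometry | None = None) -> MaskedVector:
    """Extract in-mask voxel values in the frozen (column-major) ordering."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != mask.geometry.shape:
        raise GeometryError(
            f"volume shape {volume.shape} does not match mask {mask.geometry.shape}"
        )
    if geometry is not None and not geometry.compatible_with(mask.geometry):
        raise GeometryError("volume geometry incompatible with mask geometry")
    flat = volume.reshape(-1, order="F")
    return MaskedVector(mask_id=mask.mask_id, values=flat[mask._flat_index()])


def unvectorize(vec: MaskedVector, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Scatter a masked vector back to a full 3D array, `fill` elsewhere."""
    if len(vec) != mask.n_in:
        raise ValueError(f"vector length {len(vec)} != mask n_in {mask.n_in}")
    if vec.mask_id != mask.mask_id:
        raise ValueError("vector is bound to a different mask")
    flat = np.full(int(np.prod(mask.geometry.shape)), fill, dtype=float)
    flat[mask._flat_index()] = vec.values
    return flat.reshape(mask.geometry.shape, order="F")
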