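"""Synthetic phantom cohorts with known ground-truth metabolic patterns.

Each subject volume is

    V = g * ( T + z * P_group + eps_smoothed )

where T is a shared smooth "brain" template on an ellipsoidal mask, P_group
is the group's ground-truth pattern (a sum of smooth spherical caps with
both hyper- and hypometabolic regions; zero for controls), z ~ N(1,
loading_sd^2) truncated at 0 is the subject's pattern expression loading,
eps is white Gaussian noise smoothed to a correlation length comparable to
scanner resolution, and g ~ Uniform(global_scale_range) is a global
multiplicative factor emulating dose/scanner sensitivity differences. The
demean + L2 preprocessing is exactly invariant to g, which makes the
normalization claim a provable property of the pipeline.

Group naming follows the study design the generator emulates: two patient
groups A and B (e.g. ALS and Parkinson-plus) plus healthy controls HC, with
default cohort sizes 70 / 33 / 29.

By default the noise amplitude is calibrated analytically so that the
in-mask standard deviation of the *smoothed* noise field equals the in-mask
RMS of the between-group pattern contrast (contrast-to-noise ratio 1).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import FWHM_PER_SIGMA
from .volume_io import BrainMask, VolumeGeometry, save_volume, vectorize

GROUP_CODES = {"HC": 0, "A": 1, "B": 2}

#: default ground-truth regions per group: (center_mm, radius_mm, amplitude).
#: Group A mixes cortical hypometabolism (negative) with a hypermetabolic
#: focus (positive); group B is predominantly hypometabolic in deep/posterior
#: regions. Positions are arbitrary geometry, not anatomy.
DEFAULT_REGIONS = {
    "A": [((-12.0, 18.0, 12.0), 10.0, -6.0),
          ((14.0, 16.0, 8.0), 9.0, -5.0),
          ((0.0, -24.0, -2.0), 8.0, 5.0)],
    "B": [((0.0, 2.0, 0.0), 8.0, -6.0),
          ((0.0, -14.0, -12.0), 8.0, -5.0),
          ((12.0, -8.0, -10.0), 7.0, 4.0)],
}


def default_geometry(n: int = 32, voxel_mm: float = 2.0) -> VolumeGeometry:
    """An n^3 grid of isotropic voxels centered on the world origin."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (n - 1) / 2.0
    return VolumeGeometry(shape=(n, n, n), affine=aff)


@dataclass
class PhantomSpec:
    """All knobs of the phantom generator; defaults are the study conditions."""

    geometry: VolumeGeometry = field(default_factory=default_geometry)
    mask_radii_mm: tuple[float, float, float] = (26.0, 28.0, 24.0)
    template_amplitude: float = 100.0
    pattern_regions: dict = field(default_factory=lambda: {
        g: list(v) for g, v in DEFAULT_REGIONS.items()
    })
    loading_sd: float = 0.2
    global_scale_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: float | None = None      # None -> calibrated for CNR 1
    noise_fwhm_mm: float = 6.0
    scanner_offset: np.ndarray | None = None  # optional multiplicative field
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.mask_radii_mm):
            raise ValueError("mask radii must be positive")
        lo, hi = self.global_scale_range
        if lo <= 0 or hi < lo:
            raise ValueError("global_scale_range must be a positive interval")
        for regions in self.pattern_regions.values():
            for _, radius, _ in regions:
                if radius <= 0:
                    raise ValueError("region radii must be positive")

    # -- derived, deterministic fields -------------------------------------

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        g = self.geometry
        idx = np.meshgrid(*[np.arange(s) for s in g.shape], indexing="ij")
        aff = g.affine
        xs = aff[0, 0] * idx[0] + aff[0, 1] * idx[1] + aff[0, 2] * idx[2] + aff[0, 3]
        ys = aff[1, 0] * idx[0] + aff[1, 1] * idx[1] + aff[1, 2] * idx[2] + aff[1, 3]
        zs = aff[2, 0] * idx[0] + aff[2, 1] * idx[1] + aff[2, 2] * idx[2] + aff[2, 3]
        return xs, ys, zs

    def mask(self) -> BrainMask:
        xs, ys, zs = self.world_coords()
        rx, ry, rz = self.mask_radii_mm
        rho2 = (xs / rx) ** 2 + (ys / ry) ** 2 + (zs / rz) ** 2
        return BrainMask(geometry=self.geometry, voxels=rho2 <= 1.0)

    def template(self) -> np.ndarray:
        """Smooth 'brain' background: brighter centrally, fading to the rim."""
        xs, ys, zs = self.world_coords()
        rx, ry, rz = self.mask_radii_mm
        rho2 = (xs / rx) ** 2 + (ys / ry) ** 2 + (zs / rz) ** 2
        vol = self.template_amplitude * (1.2 - 0.4 * rho2)
        vol[rho2 > 1.0] = 0.0
        return vol

    def truth_pattern(self, group: str) -> np.ndarray:
        """Ground-truth pattern volume for a group, zero-mean over the mask.

        Regions are smooth spherical caps amp * max(0, 1 - (d/r)^2),
        restricted to the mask.
        """
        if group not in GROUP_CODES:
            raise ValueError(f"unknown group: {group}")
        xs, ys, zs = self.world_coords()
        vol = np.zeros(self.geometry.shape)
        for (cx, cy, cz), radius, amp in self.pattern_regions.get(group, []):
            d2 = ((xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2) / radius**2
            vol += amp * np.clip(1.0 - d2, 0.0, None)
        m = self.mask().voxels
        vol[~m] = 0.0
        vol[m] -= vol[m].mean()
        return vol

    def smoothed_noise_gain(self) -> float:
        """sd ratio (output/input) of the noise-smoothing filter, from its
        impulse response: sqrt(sum of squared kernel weights)."""
        if self.noise_fwhm_mm == 0:
            return 1.0
        sigma = [self.noise_fwhm_mm / (v * FWHM_PER_SIGMA) for v in self.geometry.voxel_size]
        half = [int(np.ceil(4 * s)) for s in sigma]
        imp = np.zeros([2 * h + 1 for h in half])
        imp[tuple(half)] = 1.0
        resp = ndimage.gaussian_filter(imp, sigma=sigma, mode="constant")
        return float(np.sqrt((resp**2).sum()))

    def contrast_rms(self) -> float:
        """In-mask RMS of the between-group pattern contrast (A - B when
        both groups have patterns, else the single pattern)."""
        m = self.mask().voxels
        groups = [g for g in ("A", "B") if self.pattern_regions.get(g)]
        if not groups:
            raise ValueError("no pattern regions defined")
        if len(groups) == 2:
            contrast = self.truth_pattern("A") - self.truth_pattern("B")
        else:
            contrast = self.truth_pattern(groups[0])
        return float(np.sqrt((contrast[m] ** 2).mean()))

    def effective_noise_sd(self, target_cnr: float = 1.0) -> float:
        """White-noise sd used by the simulator: either the explicit
        ``noise_sd`` or the analytic calibration such that the smoothed
        noise field's sd equals contrast_rms / target_cnr."""
        if self.noise_sd is not None:
            return self.noise_sd
        return self.contrast_rms() / (target_cnr * self.smoothed_noise_gain())


@dataclass
class PhantomCohort:
    """Simulated volumes plus everything needed to score recovery."""

    spec: PhantomSpec
    volumes: list[np.ndarray]
    labels: np.ndarray        # group strings
    subject_ids: list[str]
    manifest: pd.DataFrame
    mask: BrainMask
    truth: dict               # group -> ground-truth pattern volume
    loadings: np.ndarray      # per-subject z
    global_scales: np.ndarray  # per-subject g

    @property
    def geometry(self) -> VolumeGeometry:
        return self.spec.geometry

    def manifest_hash(self) -> str:
        h = hashlib.sha1()
        h.update(self.manifest.to_csv(index=False).encode())
        for v in self.volumes:
            h.update(np.round(v, 9).tobytes())
        return h.hexdigest()[:16]


def simulate_subject(spec: PhantomSpec, group: str, subject_seed: int,
                     return_params: bool = False):
    """One phantom scan: g * (T + z*P_group + smoothed noise).

    Fully reproducible from (spec.seed, group, subject_seed).
    """
    if group not in GROUP_CODES:
        raise ValueError(f"unknown group: {group} (expected HC/A/B)")
    rng = np.random.default_rng([spec.seed, GROUP_CODES[group], subject_seed])
    lo, hi = spec.global_scale_range
    g = lo if hi == lo else rng.uniform(lo, hi)
    if spec.loading_sd > 0:
        a = (0.0 - 1.0) / spec.loading_sd  # truncate at 0
        z = float(stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=spec.loading_sd,
                                      random_state=rng))
    else:
        z = 1.0
    vol = spec.template().copy()
    if group != "HC":
        vol += z * spec.truth_pattern(group)
    sd = spec.effective_noise_sd()
    if sd > 0:
        eps = rng.normal(0.0, sd, size=spec.geometry.shape)
        if spec.noise_fwhm_mm > 0:
            sigma = [spec.noise_fwhm_mm / (v * FWHM_PER_SIGMA)
                     for v in spec.geometry.voxel_size]
            eps = ndimage.gaussian_filter(eps, sigma=sigma, mode="reflect")
        vol = vol + eps
    if spec.scanner_offset is not None:
        vol = vol * spec.scanner_offset
    vol = g * vol
    if return_params:
        return vol, {"g": g, "z": z}
    return vol


def simulate_cohort(spec: PhantomSpec | None = None, n_HC: int = 29,
                    n_A: int = 70, n_B: int = 33, seed: int | None = None) -> PhantomCohort:
    """Simulate an independent cohort; default sizes 29 HC / 70 A / 33 B."""
    spec = spec or PhantomSpec()
    if seed is not None:
        spec = PhantomSpec(**{**spec.__dict__, "seed": seed})
    if n_HC + n_A + n_B == 0:
        raise ValueError("cohort is empty")
    if n_HC < 0 or n_A < 0 or n_B < 0:
        raise ValueError("cohort sizes must be >= 0")
    volumes, labels, ids, zs, gs = [], [], [], [], []
    for group, n in (("HC", n_HC), ("A", n_A), ("B", n_B)):
        for i in range(n):
            vol, params = simulate_subject(spec, group, i, return_params=True)
            volumes.append(vol)
            labels.append(group)
            ids.append(f"{group}{i:03d}")
            zs.append(params["z"])
            gs.append(params["g"])
    manifest = pd.DataFrame({"subject_id": ids, "group": labels})
    truth = {g: spec.truth_pattern(g) for g in ("A", "B") if spec.pattern_regions.get(g)}
    return PhantomCohort(
        spec=spec, volumes=volumes, labels=np.asarray(labels),
        subject_ids=ids, manifest=manifest, mask=spec.mask(),
        truth=truth, loadings=np.asarray(zs), global_scales=np.asarray(gs),
    )


def truth_similarity(estimated, truth_volume: np.ndarray, mask: BrainMask) -> float:
    """Cosine similarity between an estimated pattern and a truth volume,
    both demeaned over the mask. ``estimated`` may be a Pattern, a
    MaskedVector, or a raw in-mask weight vector."""
    if hasattr(estimated, "weights"):      # Pattern
        est = np.asarray(estimated.weights.values, dtype=float)
    elif hasattr(estimated, "values"):     # MaskedVector
        est = np.asarray(estimated.values, dtype=float)
    else:
        est = np.asarray(estimated, dtype=float).ravel()
    if est.size != mask.n_in:
        raise ValueError("estimated pattern length does not match mask")
    tru = vectorize(np.asarray(truth_volume, dtype=float), mask).values
    est = est - est.mean()
    tru = tru - tru.mean()
    ne, nt = np.linalg.norm(est), np.linalg.norm(tru)
    if ne == 0 or nt == 0:
        raise ValueError("zero vector in cosine similarity")
    return float(est @ tru / (ne * nt))


def write_cohort(cohort: PhantomCohort, outdir) -> pd.DataFrame:
    """Write volumes, mask, truth patterns and a manifest TSV to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = cohort.geometry
    save_volume(cohort.mask.voxels.astype(float), geom, outdir / "mask.nii.gz")
    rows = []
    for sid, grp, vol in zip(cohort.subject_ids, cohort.labels, cohort.volumes):
        path = outdir / f"{sid}.nii.gz"
        save_volume(vol, geom, path)
        rows.append({"subject_id": sid, "path": str(path), "group": grp})
    for grp, tvol in cohort.truth.items():
        save_volume(tvol, geom, outdir / f"truth_{grp}.nii.gz")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
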