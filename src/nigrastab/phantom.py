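"""Synthetic QSM-like phantom cohorts.

Each phantom subject is a 3D susceptibility-like volume (parts per billion)
containing a small number of bright ellipsoidal nuclei — a stand-in for the
bilateral substantia nigra — over a dim background, plus the exact binary
support of those nuclei as the reference label.  The disease class ("PD")
has a higher and more heterogeneous interior intensity than the control
class ("HC"), emulating the excess iron deposition that makes the nucleus a
Parkinson's biomarker on QSM.  A sharp intensity rim at the nucleus
boundary gives the edge contrast that drives label-sensitivity of
downstream classifiers.

Noise is spatially correlated (smoothed white noise) so that texture
features carry nontrivial values, and every draw is reproducible from an
integer seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BinaryMask, VolumeGrid

__all__ = [
    "PhantomParams",
    "Subject",
    "Cohort",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

Diagnosis = Literal["PD", "HC"]

#: background margin (voxels) every nucleus must keep from the grid edge
EDGE_MARGIN_VOX = 3


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings for one phantom cohort.

    Intensities are in parts per billion (ppb); lengths in mm.

    Attributes
    ----------
    grid_shape : tuple of 3 ints
        Volume dimensions in voxels.
    spacing : tuple of 3 floats
        Voxel size in mm (default matches a 0.86 x 0.86 x 1.0 mm GRE
        acquisition grid).
    n_nuclei : int
        Number of ellipsoidal nuclei; 2 places a mirrored bilateral pair.
    nucleus_radius_range : (float, float)
        Semi-axis range in mm for each ellipsoid axis.
    hc_mean, pd_mean : float
        Mean interior intensity per class; ``pd_mean > hc_mean``.
    hc_sd, pd_sd : float
        Within-nucleus texture standard deviation per class; the disease
        class defaults to the larger value so both first-order and texture
        features carry class signal.
    between_subject_sd : float
        SD of a per-subject offset added to the interior mean; controls how
        separable the classes are at the cohort level.
    texture_sd_jitter, texture_corr_jitter : float
        Relative (lognormal) per-subject jitter of the interior texture
        amplitude and of the texture correlation length — iron-deposition
        patchiness varies across individuals, which also gives texture
        features realistic between-subject variance.
    background_mean, background_sd : float
        Background intensity statistics (surrounding midbrain tissue is
        dimmer than the nucleus but not zero).
    texture_correlation_length : float
        Gaussian correlation length (mm) of the noise fields.
    rim_contrast : float
        Extra intensity on the one-voxel interior shell of each nucleus;
        sharpens the boundary step.
    pv_smoothing : float
        Optional Gaussian partial-volume blur (mm) applied to the composed
        image (never to the label); 0 keeps the boundary step crisp.
    bilateral_offset_frac : float
        Lateral offset of the mirrored pair as a fraction of the grid
        extent.
    seed : int
        Default master seed when no explicit seed is given.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 32)
    spacing: tuple[float, float, float] = (0.86, 0.86, 1.0)
    n_nuclei: int = 2
    nucleus_radius_range: tuple[float, float] = (2.5, 4.2)
    hc_mean: float = 90.0
    pd_mean: float = 120.0
    hc_sd: float = 15.0
    pd_sd: float = 28.0
    between_subject_sd: float = 13.0
    texture_sd_jitter: float = 0.35
    texture_corr_jitter: float = 0.3
    background_mean: float = 40.0
    background_sd: float = 12.0
    texture_correlation_length: float = 1.5
    rim_contrast: float = 30.0
    pv_smoothing: float = 0.0
    bilateral_offset_frac: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pd_mean <= self.hc_mean:
            raise ValueError(f"pd_mean ({self.pd_mean}) must exceed hc_mean ({self.hc_mean})")
        for name in ("hc_sd", "pd_sd", "between_subject_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid nucleus_radius_range {self.nucleus_radius_range}")


@dataclass
class Subject:
    subject_id: str
    volume: VolumeGrid
    mask: BinaryMask
    diagnosis: Diagnosis


@dataclass
class Cohort:
    subjects: list[Subject]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def diagnoses(self) -> np.ndarray:
        return np.array([s.diagnosis for s in self.subjects])


def _correlated_noise(rng: np.random.Generator, shape, spacing, corr_length_mm: float) -> np.ndarray:
    """Zero-mean unit-SD noise with Gaussian spatial correlation."""
    white = rng.standard_normal(shape)
    sigma_vox = np.maximum(np.asarray(corr_length_mm) / np.asarray(spacing), 1e-6)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _nucleus_geometry(rng: np.random.Generator, params: PhantomParams):
    """Sample centers (mm) and semi-axes (mm) for the nuclei.

    For n_nuclei == 2 the pair is mirrored about the mid-sagittal (x) plane
    with mild independent jitter, mimicking a bilateral structure.
    """
    shape = np.asarray(params.grid_shape)
    spacing = np.asarray(params.spacing)
    extent = shape * spacing
    lo, hi = params.nucleus_radius_range
    centers, axes = [], []
    if params.n_nuclei == 2:
        base_off = params.bilateral_offset_frac * extent[0] + rng.uniform(-1.0, 1.0)
        for side in (-1.0, 1.0):
            c = extent / 2.0 + rng.uniform(-1.0, 1.0, size=3) * spacing
            c[0] += side * base_off
            a = rng.uniform(lo, hi, size=3)
            a *= 1.0 + rng.uniform(-0.1, 0.1, size=3)  # mild axis jitter
            centers.append(c)
            axes.append(np.clip(a, lo * 0.8, hi * 1.1))
    else:
        for _ in range(params.n_nuclei):
            a = rng.uniform(lo, hi, size=3)
            margin_mm = a + (EDGE_MARGIN_VOX + 1) * spacing
            c = rng.uniform(margin_mm, extent - margin_mm)
            centers.append(c)
            axes.append(a)
    return centers, axes


def _check_fits(center, semiaxes, params: PhantomParams) -> None:
    extent = np.asarray(params.grid_shape) * np.asarray(params.spacing)
    margin_mm = EDGE_MARGIN_VOX * np.asarray(params.spacing)
    lo = center - semiaxes - margin_mm
    hi = center + semiaxes + margin_mm
    for ax in range(3):
        if lo[ax] < 0 or hi[ax] > extent[ax]:
            raise ValueError(
                f"nucleus (center={center}, semiaxes={semiaxes}) violates the "
                f"{EDGE_MARGIN_VOX}-voxel background margin on axis {ax} "
                f"(grid extent {extent[ax]:.1f} mm)"
            )


def _voxel_centers_mm(shape, spacing):
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    return grids


def generate_subject(
    params: PhantomParams, diagnosis: Diagnosis, seed: int
) -> tuple[VolumeGrid, BinaryMask]:
    """Generate one phantom volume and its exact reference nucleus mask.

    The mask is the analytic ellipsoid support voxelized at voxel centers
    (boundary equality counts as foreground).  Identical
    ``(params, diagnosis, seed)`` yields bit-identical output.
    """
    if diagnosis not in ("PD", "HC"):
        raise ValueError(f"diagnosis must be 'PD' or 'HC', got {diagnosis!r}")
    rng = np.random.default_rng(seed)
    shape = tuple(params.grid_shape)
    spacing = np.asarray(params.spacing, dtype=float)

    centers, axes = _nucleus_geometry(rng, params)
    for c, a in zip(centers, axes):
        _check_fits(c, a, params)

    gx, gy, gz = _voxel_centers_mm(shape, spacing)
    mask = np.zeros(shape, dtype=bool)
    for c, a in zip(centers, axes):
        q = ((gx - c[0]) / a[0]) ** 2 + ((gy - c[1]) / a[1]) ** 2 + ((gz - c[2]) / a[2]) ** 2
        mask |= q <= 1.0  # ties are foreground

    mean = params.pd_mean if diagnosis == "PD" else params.hc_mean
    sd = params.pd_sd if diagnosis == "PD" else params.hc_sd
    subject_offset = params.between_subject_sd * rng.standard_normal()
    # per-subject heterogeneity of the interior texture amplitude (iron
    # deposition patchiness varies across individuals)
    sd = sd * np.exp(params.texture_sd_jitter * rng.standard_normal() - params.texture_sd_jitter**2 / 2)
    # texture scale also varies across subjects (patchiness of deposition)
    corr_len = params.texture_correlation_length * np.exp(
        params.texture_corr_jitter * rng.standard_normal() - params.texture_corr_jitter**2 / 2
    )

    bg_noise = _correlated_noise(rng, shape, spacing, corr_len)
    in_noise = _correlated_noise(rng, shape, spacing, corr_len)

    vol = params.background_mean + params.background_sd * bg_noise
    interior = mean + subject_offset + sd * in_noise
    vol = np.where(mask, interior, vol)

    if params.rim_contrast != 0 and mask.any():
        shell = mask & ~ndimage.binary_erosion(mask)
        vol = np.where(shell, vol + params.rim_contrast, vol)

    if params.pv_smoothing > 0:
        # partial-volume / reconstruction smoothing: boundary voxels take
        # intermediate values, as in real QSM, instead of a binary step
        vol = ndimage.gaussian_filter(vol, sigma=params.pv_smoothing / spacing, mode="reflect")

    volume = VolumeGrid(vol, spacing)
    ref = BinaryMask(mask.astype(np.uint8), spacing)
    return volume, ref


def generate_cohort(n_pd: int, n_hc: int, params: PhantomParams, seed: int) -> Cohort:
    """Generate a labeled cohort with per-subject seeds derived from ``seed``."""
    if n_pd < 1 or n_hc < 1:
        raise ValueError("need at least one subject per class")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_pd + n_hc)]
    subjects: list[Subject] = []
    for i in range(n_pd):
        vol, msk = generate_subject(params, "PD", child_seeds[i])
        subjects.append(Subject(f"PD{i + 1:03d}", vol, msk, "PD"))
    for j in range(n_hc):
        vol, msk = generate_subject(params, "HC", child_seeds[n_pd + j])
        subjects.append(Subject(f"HC{j + 1:03d}", vol, msk, "HC"))
    return Cohort(subjects)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> Path:
    """Persist volumes/masks as NIfTI plus a CSV manifest; returns manifest path."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc
    rows = []
    for s in cohort:
        vpath = directory / f"{s.subject_id}_qsm.nii.gz"
        mpath = directory / f"{s.subject_id}_sn.nii.gz"
        aff = _affine(s.volume.spacing, s.volume.origin)
        nib.save(nib.Nifti1Image(s.volume.values, aff), str(vpath))
        nib.save(nib.Nifti1Image(s.mask.values, aff), str(mpath))
        rows.append(
            {
                "subject_id": s.subject_id,
                "volume_path": vpath.name,
                "mask_path": mpath.name,
                "diagnosis": s.diagnosis,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=["subject_id", "volume_path", "mask_path", "diagnosis"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_cohort(manifest_path: str | os.PathLike) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (arrays round-trip exactly)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    subjects = []
    for _, row in df.iterrows():
        vimg = nib.load(str(base / row["volume_path"]))
        mimg = nib.load(str(base / row["mask_path"]))
        spacing = np.asarray(vimg.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(vimg.affine[:3, 3], dtype=float)
        vol = VolumeGrid(np.asarray(vimg.dataobj, dtype=np.float64), spacing, origin)
        msk = BinaryMask(np.asarray(mimg.dataobj).astype(np.uint8), spacing, origin)
        subjects.append(Subject(str(row["subject_id"]), vol, msk, str(row["diagnosis"])))
    return Cohort(subjects)


def zero_noise_params(pd_mean: float = 120.0, hc_mean: float = 90.0, **kw) -> PhantomParams:
    """Degenerate noise-free settings (flat interiors, zero background)."""
    return PhantomParams(
        pd_mean=pd_mean,
        hc_mean=hc_mean,
        hc_sd=0.0,
        pd_sd=0.0,
        between_subject_sd=0.0,
        background_mean=0.0,
        background_sd=0.0,
        rim_contrast=0.0,
        pv_smoothing=0.0,
        **kw,
    )
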