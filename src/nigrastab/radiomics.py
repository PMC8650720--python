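"""Radiomics-and-logistic-regression classification arm.

Masked feature extraction from the QSM-like volume, an ICC(2,1) screen
that keeps only features robust across label sources, and an
L2-regularized logistic model selected by recursive feature elimination
(RFE).

The extractor computes a documented ~30-feature subset spanning
first-order intensity statistics, shape descriptors, and a 3D gray-level
co-occurrence matrix (GLCM) family (1-voxel offsets averaged over the 13
unique 3D directions, fixed 16-bin discretization over the in-mask
range).  A full production radiomics configuration can be substituted:
anything that maps ``(volume, mask) -> pandas.Series`` plugs into the
downstream screen and model unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.linear_model import LogisticRegression

from .grids import BinaryMask, VolumeGrid
from .metrics import ICC_DEGENERATE, icc_2_1
from .phantom import Cohort

__all__ = [
    "extract_features",
    "cohort_feature_matrix",
    "icc_screen",
    "ScreenResult",
    "LinearClassifier",
    "rfe_train",
    "predict_scores",
    "N_GLCM_LEVELS",
]

log = logging.getLogger(__name__)

N_GLCM_LEVELS = 16

# 13 unique 3D neighbor directions (half of the 26-neighborhood)
_DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _first_order(x: np.ndarray) -> dict[str, float]:
    n = x.size
    hist, _ = np.histogram(x, bins=N_GLCM_LEVELS)
    p = hist / n
    p = p[p > 0]
    feats = {
        "fo_mean": x.mean(),
        "fo_sd": x.std(ddof=0),
        "fo_variance": x.var(ddof=0),
        "fo_median": np.median(x),
        "fo_p10": np.percentile(x, 10),
        "fo_p90": np.percentile(x, 90),
        "fo_min": x.min(),
        "fo_max": x.max(),
        "fo_range": x.max() - x.min(),
        "fo_iqr": np.percentile(x, 75) - np.percentile(x, 25),
        "fo_energy": float((x**2).sum()),
        "fo_rms": float(np.sqrt((x**2).mean())),
        "fo_entropy": float(-(p * np.log2(p)).sum()),
        "fo_uniformity": float((p**2).sum()),
        "fo_skewness": float(stats.skew(x)) if x.std() > 0 else 0.0,
        "fo_kurtosis": float(stats.kurtosis(x)) if x.std() > 0 else 0.0,
        "fo_robust_mad": float(np.mean(np.abs(x - np.median(x)))),
    }
    return {k: float(v) for k, v in feats.items()}


def _shape(mask: np.ndarray, spacing: np.ndarray) -> dict[str, float]:
    voxel_vol = float(np.prod(spacing))
    n = int(mask.sum())
    surface = mask & ~ndimage.binary_erosion(mask)
    coords = np.argwhere(mask) * spacing  # voxel centers, mm
    centered = coords - coords.mean(axis=0)
    if n > 3:
        cov = centered.T @ centered / n
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ev = np.maximum(ev, 0.0)
        elongation = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 0.0
        flatness = float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else 0.0
    else:
        elongation = flatness = 0.0
    surf_coords = np.argwhere(surface) * spacing
    if len(surf_coords) >= 2:
        # max 3D diameter over surface voxel centers
        d2 = ((surf_coords[:, None, :] - surf_coords[None, :, :]) ** 2).sum(-1)
        max_diam = float(np.sqrt(d2.max()))
    else:
        max_diam = 0.0
    return {
        "sh_volume_mm3": n * voxel_vol,
        "sh_voxel_count": float(n),
        "sh_surface_voxels": float(surface.sum()),
        "sh_elongation": elongation,
        "sh_flatness": flatness,
        "sh_max_diameter": max_diam,
    }


def glcm_counts(binned: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int],
                n_levels: int = N_GLCM_LEVELS) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset; both voxels in mask."""
    dx, dy, dz = direction
    sl_a = tuple(slice(max(0, -d), min(s, s - d)) for d, s in zip(direction, binned.shape))
    sl_b = tuple(slice(max(0, d), min(s, s + d)) for d, s in zip(direction, binned.shape))
    a, b = binned[sl_a], binned[sl_b]
    valid = mask[sl_a] & mask[sl_b]
    counts = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    return counts + counts.T  # symmetric


def _glcm_features(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total == 0:
        return {k: 0.0 for k in (
            "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
            "glcm_dissimilarity", "glcm_entropy", "glcm_cluster_shade", "glcm_cluster_prominence",
        )}
    p = counts / total
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    sd_i = np.sqrt(((i - mu_i) ** 2 * p).sum())
    sd_j = np.sqrt(((j - mu_j) ** 2 * p).sum())
    contrast = ((i - j) ** 2 * p).sum()
    if sd_i > 0 and sd_j > 0:
        correlation = (((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j)
    else:
        correlation = 0.0
    pz = p[p > 0]
    s = i + j - mu_i - mu_j
    return {
        "glcm_contrast": float(contrast),
        "glcm_correlation": float(correlation),
        "glcm_energy": float((p**2).sum()),
        "glcm_homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "glcm_dissimilarity": float((np.abs(i - j) * p).sum()),
        "glcm_entropy": float(-(pz * np.log2(pz)).sum()),
        "glcm_cluster_shade": float((s**3 * p).sum()),
        "glcm_cluster_prominence": float((s**4 * p).sum()),
    }


def extract_features(volume: VolumeGrid, mask: BinaryMask) -> pd.Series:
    """Deterministic feature vector for one (volume, mask) pair.

    Returns a named :class:`pandas.Series`; identical inputs give
    identical output.  If the in-mask intensity range collapses to fewer
    than 2 gray levels, texture features are defined as 0.
    """
    m = mask.as_bool()
    if not m.any():
        raise ValueError("empty mask: no voxels to extract features from")
    vals = volume.values[m]
    feats: dict[str, float] = {}
    feats.update(_first_order(vals))
    feats.update(_shape(m, np.asarray(volume.spacing)))

    if vals.max() > vals.min():
        # discretize over the in-mask range only
        lo, hi = vals.min(), vals.max()
        b = np.clip(np.floor((volume.values - lo) / (hi - lo) * N_GLCM_LEVELS), 0,
                    N_GLCM_LEVELS - 1).astype(int)
        counts = np.zeros((N_GLCM_LEVELS, N_GLCM_LEVELS))
        for d in _DIRECTIONS:
            counts += glcm_counts(b, m, d)
        feats.update(_glcm_features(counts))
    else:
        log.warning("constant in-mask intensity: GLCM features set to 0")
        feats.update(_glcm_features(np.zeros((N_GLCM_LEVELS, N_GLCM_LEVELS))))
        feats["glcm_energy"] = 1.0  # single gray level: fully uniform texture
    return pd.Series(feats, dtype=float)


def cohort_feature_matrix(cohort: Cohort, masks: dict[str, BinaryMask]) -> pd.DataFrame:
    """Subjects-by-features matrix using one mask per subject."""
    rows = {s.subject_id: extract_features(s.volume, masks[s.subject_id]) for s in cohort}
    return pd.DataFrame(rows).T.sort_index()


@dataclass
class ScreenResult:
    kept_names: list[str]
    icc_values: pd.Series  # per feature: minimum ICC over all pairings

    @property
    def n_kept(self) -> int:
        return len(self.kept_names)


def icc_screen(
    reference: pd.DataFrame,
    perturbed: Sequence[pd.DataFrame] | pd.DataFrame,
    threshold: float = 0.8,
) -> ScreenResult:
    """Keep features whose ICC(2,1) between the reference label source and
    every perturbed source exceeds ``threshold`` (strict inequality).

    Each perturbed matrix is paired with the reference as the two "raters";
    a feature survives only if it passes for all pairings.  Degenerate
    (constant) features fail the screen rather than raising.
    """
    if isinstance(perturbed, pd.DataFrame):
        perturbed = [perturbed]
    mins = pd.Series(np.inf, index=reference.columns)
    for other in perturbed:
        if list(other.columns) != list(reference.columns):
            raise ValueError("feature names differ between label sources")
        if not reference.index.equals(other.index):
            raise ValueError("subject sets differ between label sources")
        for name in reference.columns:
            ratings = np.column_stack([reference[name].values, other[name].values])
            v = icc_2_1(ratings)
            if v == ICC_DEGENERATE:
                v = -np.inf
            mins[name] = min(mins[name], v)
    kept = [n for n in reference.columns if mins[n] > threshold]
    return ScreenResult(kept, mins)


@dataclass
class LinearClassifier:
    """Standardized logistic model over a selected feature subset."""

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray


@dataclass
class RfeConfig:
    C: float = 1.0
    max_iter: int = 500
    #: balanced class weights keep the decision threshold calibrated under
    #: the cohort's disease-majority imbalance
    class_weight: str | None = "balanced"


def _fit_lr(Xs: np.ndarray, y01: np.ndarray, cfg: RfeConfig) -> LogisticRegression:
    lr = LogisticRegression(C=cfg.C, solver="lbfgs", max_iter=cfg.max_iter,
                            class_weight=cfg.class_weight)
    lr.fit(Xs, y01)
    return lr


def rfe_train(
    X: pd.DataFrame, y: Sequence[str], n_final: int = 10, cfg: RfeConfig | None = None
) -> LinearClassifier:
    """Recursive feature elimination around an L2 logistic model.

    Features are standardized internally; at each step the feature with
    the smallest standardized |weight| is dropped (ties broken by
    lexicographically greatest name) until ``n_final`` remain, then the
    model is refit on the survivors.  Deterministic for fixed inputs.
    """
    cfg = cfg or RfeConfig()
    y01 = (np.asarray(y) == "PD").astype(int)
    if y01.sum() < 2 or (1 - y01).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    names = list(X.columns)
    if n_final > len(names):
        log.warning("n_final (%d) exceeds feature count (%d): keeping all features",
                    n_final, len(names))
    n_final = min(n_final, len(names))

    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0).replace(0.0, 1.0)

    current = list(names)
    while len(current) > n_final:
        Xs = ((X[current] - center[current]) / scale[current]).values
        lr = _fit_lr(Xs, y01, cfg)
        w = np.abs(lr.coef_.ravel())
        min_w = w.min()
        tied = [current[i] for i in range(len(current)) if w[i] <= min_w + 1e-15]
        drop = max(tied)  # lexicographic tie-break
        current.remove(drop)

    Xs = ((X[current] - center[current]) / scale[current]).values
    lr = _fit_lr(Xs, y01, cfg)
    return LinearClassifier(
        feature_names=list(current),
        weights=lr.coef_.ravel().copy(),
        intercept=float(lr.intercept_[0]),
        center=center[current].values.copy(),
        scale=scale[current].values.copy(),
    )


def predict_scores(model: LinearClassifier, X: pd.DataFrame) -> np.ndarray:
    """P(PD) per row via the stored standardization and logistic transform."""
    missing = [n for n in model.feature_names if n not in X.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    Z = (X[model.feature_names].values - model.center) / model.scale
    lin = Z @ model.weights + model.intercept
    return 1.0 / (1.0 + np.exp(-lin))
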