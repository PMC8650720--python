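"""Evaluation statistics for label-stability analysis.

Implements the overlap, agreement and classification measures the study
design rests on: the Dice coefficient, signed Euclidean distance maps,
ICC(2,1) feature-robustness screening, the classification consistency
index (CCI) between predictions under two label sources, the standard
binary-classification panel (accuracy / AUC / balanced accuracy /
sensitivity / specificity), and matched-samples t-tests with
multiple-comparison correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import BinaryMask, VolumeGrid

__all__ = [
    "dice_coefficient",
    "signed_distance",
    "icc_2_1",
    "ICC_DEGENERATE",
    "cci",
    "cci_matrix",
    "classification_panel",
    "auc_rank",
    "paired_comparison",
    "PredictionTable",
    "MetricsPanel",
]

#: sentinel returned by :func:`icc_2_1` for a degenerate (zero-variance)
#: rating matrix; compares below any real ICC so the feature fails screens
ICC_DEGENERATE = -np.inf

POSITIVE_CLASS = "PD"
NEGATIVE_CLASS = "HC"


def _mask_array(m) -> np.ndarray:
    if isinstance(m, BinaryMask):
        return m.as_bool()
    return np.asarray(m).astype(bool)


def dice_coefficient(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks give 1.0."""
    aa, bb = _mask_array(a), _mask_array(b)
    if aa.shape != bb.shape:
        raise ValueError(f"shape mismatch {aa.shape} vs {bb.shape}")
    denom = aa.sum() + bb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(aa, bb).sum() / denom)


def signed_distance(mask: BinaryMask, spacing=None) -> VolumeGrid:
    """Signed Euclidean distance (mm) to the nearest voxel center across the
    mask boundary: negative inside the mask, positive outside.

    A background voxel's value is its distance to the nearest foreground
    voxel center; a foreground voxel's value is minus its distance to the
    nearest background voxel center (so boundary voxels are at -spacing,
    not 0).  Anisotropic spacing is honored.
    """
    arr = _mask_array(mask)
    if spacing is None:
        spacing = mask.spacing if isinstance(mask, BinaryMask) else np.ones(3)
    spacing = np.asarray(spacing, dtype=float)
    if arr.all() or not arr.any():
        raise ValueError("mask must contain both foreground and background voxels")
    outside = ndimage.distance_transform_edt(~arr, sampling=spacing)
    inside = ndimage.distance_transform_edt(arr, sampling=spacing)
    sd = outside - inside
    return VolumeGrid(sd, spacing)


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects x k raters) matrix (k = 2 when screening
    a feature under two label sources).  Computed from the two-way ANOVA
    decomposition::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    A constant matrix (no subject and no residual variance) has no defined
    ICC; the sentinel :data:`ICC_DEGENERATE` is returned so the value fails
    any "> threshold" screen.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be n x k with k >= 2")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings must be finite")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or not np.isfinite(denom):
        return ICC_DEGENERATE
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# prediction tables


@dataclass
class PredictionTable:
    """Long-format per-(subject, label-source) predictions.

    Columns: subject_id, label_source, true_class, predicted_class,
    score (P(positive class) in [0, 1]); optional split columns
    (permutation, fold) for cross-validation bookkeeping.
    """

    df: pd.DataFrame

    REQUIRED = ("subject_id", "label_source", "true_class", "predicted_class", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"PredictionTable missing columns {missing}")

    @classmethod
    def empty(cls, extra_cols=("permutation", "fold")) -> "PredictionTable":
        cols = list(cls.REQUIRED) + list(extra_cols)
        return cls(pd.DataFrame(columns=cols))

    def append_rows(self, rows: list[dict]) -> None:
        new = pd.DataFrame(rows)
        self.df = new if self.df.empty else pd.concat([self.df, new], ignore_index=True)

    def source(self, label_source) -> pd.DataFrame:
        return self.df[self.df["label_source"] == label_source]

    def sources(self) -> list:
        return list(pd.unique(self.df["label_source"]))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionTable":
        return cls(pd.read_csv(path))


def _agreement_key(df: pd.DataFrame) -> pd.DataFrame:
    cols = ["subject_id"]
    for extra in ("permutation", "fold"):
        if extra in df.columns:
            cols.append(extra)
    return df.set_index(cols)


def cci(preds_a: pd.DataFrame, preds_b: pd.DataFrame) -> float:
    """Classification consistency index between two label sources.

    Fraction of test subjects whose predicted diagnosis agrees between the
    two sources (1 - normalized Hamming distance).  Both slices must cover
    the identical set of (subject, split) test instances.
    """
    a = _agreement_key(preds_a)["predicted_class"].sort_index()
    b = _agreement_key(preds_b)["predicted_class"].sort_index()
    if len(a) == 0:
        raise ValueError("empty prediction slices")
    if not a.index.equals(b.index):
        only_a = a.index.difference(b.index)
        only_b = b.index.difference(a.index)
        raise ValueError(
            f"subject sets differ: {len(only_a)} only in A (e.g. {list(only_a[:3])}), "
            f"{len(only_b)} only in B (e.g. {list(only_b[:3])})"
        )
    return float((a.values == b.values).mean())


def cci_matrix(table: PredictionTable, sources=None) -> pd.DataFrame:
    """Pairwise CCI over label sources; symmetric with unit diagonal."""
    if sources is None:
        sources = table.sources()
    n = len(sources)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = cci(table.source(sources[i]), table.source(sources[j]))
    return pd.DataFrame(vals, index=sources, columns=sources)


# ---------------------------------------------------------------------------
# classification panel


def auc_rank(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC as P(random positive score > random negative score), ties 1/2.

    Rank (Mann-Whitney) formulation; equals brute-force pair enumeration.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: both classes must be present")
    allscores = np.concatenate([pos, neg])
    ranks = stats.rankdata(allscores)  # average ranks handle ties as 1/2
    r_pos = ranks[: len(pos)].sum()
    n_p, n_n = len(pos), len(neg)
    u = r_pos - n_p * (n_p + 1) / 2.0
    return float(u / (n_p * n_n))


@dataclass
class MetricsPanel:
    accuracy: float
    auc: float
    bac: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "bac": self.bac,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def classification_panel(preds: pd.DataFrame, threshold: float = 0.5) -> MetricsPanel:
    """Accuracy, AUC, balanced accuracy, sensitivity (PD recall) and
    specificity (HC recall) for one test slice.

    ``preds`` needs columns true_class, predicted_class, score; both true
    classes must be present (AUC is undefined otherwise).
    """
    y = preds["true_class"].values
    yhat = preds["predicted_class"].values
    s = preds["score"].values.astype(float)
    is_pos = y == POSITIVE_CLASS
    if is_pos.all() or not is_pos.any():
        raise ValueError("single-class slice: AUC undefined")
    acc = float((y == yhat).mean())
    sens = float((yhat[is_pos] == POSITIVE_CLASS).mean())
    spec = float((yhat[~is_pos] == NEGATIVE_CLASS).mean())
    auc = auc_rank(s[is_pos], s[~is_pos])
    return MetricsPanel(acc, auc, (sens + spec) / 2.0, sens, spec)


def paired_comparison(
    metric_per_split_a, metric_per_split_b, n_comparisons: int = 1
) -> tuple[float, float]:
    """Matched-samples t-test on per-split metrics, Bonferroni-corrected.

    Returns ``(t_statistic, corrected_p)`` with ``corrected_p =
    min(1, p * n_comparisons)``; correction never lowers p.  Identical
    inputs (zero-variance differences) give ``(0.0, 1.0)``.
    """
    a = np.asarray(metric_per_split_a, dtype=float)
    b = np.asarray(metric_per_split_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if len(a) < 3:
        raise ValueError("need at least 3 paired splits")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return (0.0, 1.0) if np.allclose(d, 0.0) else (np.inf * np.sign(d.mean()), 0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(min(1.0, p * n_comparisons))
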