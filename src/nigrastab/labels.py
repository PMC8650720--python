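"""Dice-controlled label perturbation.

Families of substantia-nigra labels at prescribed Dice levels are produced
by warping each subject's reference mask through a smooth random
displacement field whose magnitude is solved so that the achieved Dice
against the reference hits the target.  All levels for a subject share one
field with increasing magnitude, so the family is a nested, gradual
deviation from the reference — the same two properties (smoothness,
gradual deviation) that a registration-derived deformation between a
manual and an automatic label would have.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import BinaryMask
from .metrics import dice_coefficient
from .phantom import Cohort

__all__ = [
    "DisplacementField",
    "LabelLevel",
    "LabelSeries",
    "random_smooth_field",
    "warp_mask",
    "solve_alpha_for_dice",
    "make_label_series",
    "DEFAULT_TARGETS",
]

DEFAULT_TARGETS = (0.975, 0.946, 0.920, 0.897, 0.872)


@dataclass
class DisplacementField:
    """Smooth per-voxel displacement, in mm, on a mask's grid.

    ``vectors`` has shape (3, nx, ny, nz); the maximum displacement
    magnitude is normalized to 1 mm, so a scalar multiplier alpha expresses
    the peak deformation in mm.
    """

    vectors: np.ndarray
    smoothness_sigma: float
    seed: int

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.vectors**2).sum(axis=0))


def random_smooth_field(
    shape: Sequence[int], spacing: Sequence[float], smoothness_sigma: float, seed: int
) -> DisplacementField:
    """Zero-mean smoothed Gaussian noise field, peak magnitude 1 mm."""
    if smoothness_sigma <= 0:
        raise ValueError("smoothness_sigma must be > 0")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(spacing, dtype=float)
    sigma_vox = smoothness_sigma / spacing
    comps = []
    for _ in range(3):
        w = rng.standard_normal(tuple(shape))
        s = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="reflect")
        comps.append(s - s.mean())
    vec = np.stack(comps)
    maxmag = np.sqrt((vec**2).sum(axis=0)).max()
    if maxmag > 0:
        vec /= maxmag
    return DisplacementField(vec, smoothness_sigma, seed)


def warp_mask(mask: BinaryMask, field: DisplacementField, alpha: float) -> BinaryMask:
    """Resample ``mask`` through the displacement ``alpha * field``.

    The binary mask is interpolated trilinearly as a real-valued image at
    the displaced sample positions and thresholded at 0.5 (ties
    foreground); outside-grid samples read 0.  ``alpha = 0`` returns the
    mask unchanged.
    """
    if field.grid_shape != mask.shape:
        raise ValueError(f"field grid {field.grid_shape} != mask shape {mask.shape}")
    if alpha == 0:
        return BinaryMask(mask.values.copy(), mask.spacing, mask.origin)
    spacing = np.asarray(mask.spacing, dtype=float)
    idx = np.indices(mask.shape, dtype=float)
    # displacement is in mm; convert to index units per axis
    coords = idx + alpha * field.vectors / spacing[:, None, None, None]
    sampled = ndimage.map_coordinates(
        mask.values.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    )
    return BinaryMask((sampled >= 0.5).astype(np.uint8), mask.spacing, mask.origin)


def solve_alpha_for_dice(
    mask: BinaryMask,
    field: DisplacementField,
    target_dice: float,
    tol: float = 0.005,
    alpha_max: float = 5.0,
    max_iter: int = 60,
) -> tuple[float, BinaryMask, float]:
    """Find the field magnitude whose warped mask achieves a target Dice.

    Bisection over ``alpha`` in [0, alpha_max] exploits that the achieved
    Dice is empirically non-increasing in the deformation magnitude; if
    non-monotonicity is detected at bisection resolution, a dense grid
    search over 200 magnitudes is used instead.

    Returns ``(alpha, warped_mask, achieved_dice)``.
    """
    if not (0 < target_dice < 1):
        raise ValueError(f"target_dice must be in (0, 1), got {target_dice}")
    if tol <= 0:
        raise ValueError("tol must be > 0")

    def achieved(a: float) -> tuple[float, BinaryMask]:
        w = warp_mask(mask, field, a)
        return dice_coefficient(mask, w), w

    d_hi, w_hi = achieved(alpha_max)
    if d_hi > target_dice + tol:
        raise ValueError(
            f"target Dice {target_dice} unreachable: Dice at alpha_max={alpha_max} "
            f"is still {d_hi:.4f}; increase alpha_max or use a rougher field"
        )

    lo, hi = 0.0, alpha_max
    best = (alpha_max, w_hi, d_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid, w_mid = achieved(mid)
        if abs(d_mid - target_dice) < abs(best[2] - target_dice):
            best = (mid, w_mid, d_mid)
        if abs(d_mid - target_dice) <= tol:
            return mid, w_mid, d_mid
        if d_mid > target_dice:
            lo = mid
        else:
            hi = mid

    # Bisection assumes Dice(alpha) is non-increasing; random fields can
    # fold at large alpha and break that, so fall back to a dense scan.
    for a in np.linspace(0.0, alpha_max, 200):
        d, w = achieved(a)
        if abs(d - target_dice) < abs(best[2] - target_dice):
            best = (a, w, d)
        if abs(d - target_dice) <= tol:
            return a, w, d
    return best


@dataclass
class LabelLevel:
    """One rung of a label series: all subjects' masks at one Dice target."""

    target_dice: float
    masks: dict[str, BinaryMask]
    alpha: dict[str, float]
    achieved_dice: dict[str, float]

    @property
    def achieved_dice_mean(self) -> float:
        return float(np.mean(list(self.achieved_dice.values())))


@dataclass
class LabelSeries:
    """Ordered label family, reference level (target 1.0) first."""

    levels: list[LabelLevel]
    seed: int

    def __post_init__(self) -> None:
        targets = [lv.target_dice for lv in self.levels]
        if targets != sorted(targets, reverse=True):
            raise ValueError("levels must be sorted by decreasing target Dice")
        if targets[0] != 1.0:
            raise ValueError("first level must be the unperturbed reference (target 1.0)")

    @property
    def targets(self) -> list[float]:
        return [lv.target_dice for lv in self.levels]

    @property
    def reference(self) -> LabelLevel:
        return self.levels[0]

    def level(self, target: float) -> LabelLevel:
        for lv in self.levels:
            if abs(lv.target_dice - target) < 1e-9:
                return lv
        raise KeyError(f"no level with target {target}")

    def masks_for(self, subject_id: str) -> list[BinaryMask]:
        return [lv.masks[subject_id] for lv in self.levels]


def make_label_series(
    cohort: Cohort,
    targets: Sequence[float] = DEFAULT_TARGETS,
    tol: float = 0.005,
    seed: int = 0,
    smoothness_sigma: float = 3.0,
    alpha_max: float = 5.0,
) -> LabelSeries:
    """Build the perturbed-label family for a whole cohort.

    One smooth field per subject (seed-derived); every level for a subject
    reuses that field with an increasing magnitude, giving a nested gradual
    deviation whose achieved Dice hits each target within ``tol``.
    """
    targets = list(targets)
    if any(not (0 < t < 1) for t in targets):
        raise ValueError("targets must be in (0, 1); the 1.0 reference level is implicit")
    if targets != sorted(targets, reverse=True) or len(set(targets)) != len(targets):
        raise ValueError("targets must be strictly decreasing")

    ss = np.random.SeedSequence(seed)
    subject_seeds = {
        s.subject_id: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(cohort, ss.spawn(len(cohort)))
    }

    ref_masks = {s.subject_id: s.mask for s in cohort}
    levels = [
        LabelLevel(
            1.0,
            {sid: BinaryMask(m.values.copy(), m.spacing, m.origin) for sid, m in ref_masks.items()},
            {sid: 0.0 for sid in ref_masks},
            {sid: 1.0 for sid in ref_masks},
        )
    ]
    per_level: dict[float, LabelLevel] = {
        t: LabelLevel(t, {}, {}, {}) for t in targets
    }
    for s in cohort:
        field = random_smooth_field(
            s.mask.shape, s.mask.spacing, smoothness_sigma, subject_seeds[s.subject_id]
        )
        for t in targets:
            try:
                a, w, d = solve_alpha_for_dice(s.mask, field, t, tol=tol, alpha_max=alpha_max)
            except ValueError as exc:
                raise ValueError(f"subject {s.subject_id}: {exc}") from exc
            lv = per_level[t]
            lv.masks[s.subject_id] = w
            lv.alpha[s.subject_id] = a
            lv.achieved_dice[s.subject_id] = d
    levels.extend(per_level[t] for t in targets)
    return LabelSeries(levels, seed)
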