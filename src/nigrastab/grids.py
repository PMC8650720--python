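"""Voxel-grid containers shared by every module.

A :class:`VolumeGrid` carries a 3D scalar image (QSM-like susceptibility in
parts per billion, probability maps, distance maps) together with its voxel
spacing and world origin; a :class:`BinaryMask` is the companion {0,1}
label volume on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "BinaryMask"]

_MIN_DIM = 8


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must have 3 components, got {v.size}")
    return v


@dataclass
class VolumeGrid:
    """3D scalar volume with geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities; finite.
    spacing : array-like of 3 floats
        Voxel size in mm along each axis; strictly positive.
    origin : array-like of 3 floats, optional
        World coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if min(self.values.shape) < _MIN_DIM:
            raise ValueError(f"all dimensions must be >= {_MIN_DIM}, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """Binary label volume on the same grid as its paired :class:`VolumeGrid`."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {uniq[:5]}")
        self.values = arr.astype(np.uint8)
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)
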