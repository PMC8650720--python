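"""Convolutional classification arm (PDNet).

A small 3D feature extractor plus a two-layer classifier head, with the
two input-conditioning modes whose stability this package compares:

``masked``
    the ROI volume is multiplied by the binary SN label (background set
    to zero, so label edges appear in the input) and pooled with global
    average pooling;

``gated``
    the un-zeroed ROI volume is encoded once, and the label enters only
    as a spatial gate on the extractor feature maps ("gated pooling"), so
    perturbations strictly outside the gate support cannot change the
    pooled features.

The extractor's first layer is fixed at 6 channels / 5x5x5 kernel /
stride 1; all layers are stride 1 with same padding, so the feature-map
grid aligns voxel-for-voxel with the input ROI and a mask cropped with
the same geometry is a valid gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import nn
from .grids import BinaryMask, VolumeGrid

__all__ = [
    "ExtractorConfig",
    "TrainConfig",
    "RoiGeometry",
    "crop_roi",
    "center_roi",
    "crop_like",
    "normalize_roi",
    "znormalize",
    "PPB_SCALE",
    "PDNet",
    "TrainedClassifier",
    "masked_forward",
    "gated_forward",
    "gated_pool",
    "train_classifier",
]

Mode = Literal["masked", "gated"]


@dataclass(frozen=True)
class ExtractorConfig:
    """Extractor topology; first conv spec is fixed to (6, 5, 1)."""

    input_roi_shape: tuple[int, int, int] = (32, 32, 24)
    conv_specs: tuple[tuple[int, int, int], ...] = ((6, 5, 1), (8, 3, 1), (12, 3, 1))
    use_norm: bool = True
    head_norm: bool = True
    head_hidden: int = 16
    margin: int = 4

    def __post_init__(self) -> None:
        if self.conv_specs[0] != (6, 5, 1):
            raise ValueError("first conv spec must be (6 channels, 5x5x5 kernel, stride 1)")
        if any(s != 1 for _, _, s in self.conv_specs):
            raise ValueError("only stride 1 supported (feature grid must align with ROI)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 18
    batch_size: int = 8
    lr: float = 1e-2
    weight_decay: float = 1e-3
    flip_augment: bool = True
    shift_augment: int = 1  # max |voxels| of random training translation
    seed: int = 0


@dataclass(frozen=True)
class RoiGeometry:
    """Where an ROI window sits in the source grid (for reproducibility)."""

    start: tuple[int, int, int]  # window start index in source grid (may be negative)
    roi_shape: tuple[int, int, int]
    source_shape: tuple[int, int, int]


def _window(arr: np.ndarray, start, shape, fill=0.0) -> np.ndarray:
    """Extract a window with zero padding where it leaves the source grid."""
    out = np.full(shape, fill, dtype=arr.dtype)
    src_lo = [max(0, s) for s in start]
    src_hi = [min(dim, s + w) for s, w, dim in zip(start, shape, arr.shape)]
    dst_lo = [sl - s for sl, s in zip(src_lo, start)]
    dst_hi = [dl + (sh - sl) for dl, sl, sh in zip(dst_lo, src_lo, src_hi)]
    if all(hi > lo for lo, hi in zip(src_lo, src_hi)):
        out[tuple(slice(l, h) for l, h in zip(dst_lo, dst_hi))] = arr[
            tuple(slice(l, h) for l, h in zip(src_lo, src_hi))
        ]
    return out


def crop_roi(
    volume: VolumeGrid,
    mask: BinaryMask,
    margin: int = 4,
    roi_shape: Sequence[int] = (32, 32, 24),
) -> tuple[np.ndarray, np.ndarray, RoiGeometry]:
    """Crop a fixed-shape ROI around the mask's dilated bounding box.

    The mask bounding box is dilated by ``margin`` voxels and clipped to
    the grid; the ROI window of ``roi_shape`` is centered on the mask
    centroid (rounded) and zero-padded where it leaves the grid — the
    centroid moves far less than the bounding box under boundary
    perturbations, so two similar labels produce nearly identical crops.
    Volume and mask are cropped with identical geometry.
    """
    m = mask.as_bool()
    if not m.any():
        raise ValueError("empty mask: cannot define an ROI")
    idx = np.argwhere(m)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin, np.array(m.shape) - 1)
    box = hi - lo + 1
    if np.any(box > np.asarray(roi_shape)):
        # dilated box larger than the ROI window: fall back to box center
        center = (lo + hi) // 2
    else:
        center = np.rint(idx.mean(axis=0)).astype(int)
    start = tuple(int(c - s // 2) for c, s in zip(center, roi_shape))
    geom = RoiGeometry(start, tuple(roi_shape), m.shape)
    vol_roi = _window(volume.values, start, tuple(roi_shape))
    mask_roi = _window(m.astype(np.float64), start, tuple(roi_shape))
    return vol_roi, mask_roi, geom


def center_roi(volume: VolumeGrid, roi_shape: Sequence[int]) -> tuple[np.ndarray, RoiGeometry]:
    """Mask-free ROI: a window of ``roi_shape`` centered on the grid."""
    start = tuple(int(d // 2 - s // 2) for d, s in zip(volume.shape, roi_shape))
    geom = RoiGeometry(start, tuple(roi_shape), volume.shape)
    return _window(volume.values, start, tuple(roi_shape)), geom


def crop_like(arr: np.ndarray, geom: RoiGeometry) -> np.ndarray:
    """Crop another same-grid array with a previously recorded geometry."""
    return _window(np.asarray(arr, dtype=np.float64), geom.start, geom.roi_shape)


#: fixed intensity scale (ppb) dividing network inputs; QSM is an absolute
#: quantitative scale, so normalization must not be per-image adaptive — a
#: per-ROI z-score would cancel exactly the iron-load contrast that carries
#: the diagnosis.
PPB_SCALE = 100.0


def normalize_roi(roi: np.ndarray, ppb_scale: float = PPB_SCALE) -> np.ndarray:
    """Scale ROI intensities to O(1) by a fixed susceptibility constant."""
    return roi / ppb_scale


def znormalize(roi: np.ndarray) -> np.ndarray:
    """Per-ROI z-score (kept for comparison; removes absolute-scale signal)."""
    sd = roi.std()
    if sd == 0:
        return roi - roi.mean()
    return (roi - roi.mean()) / sd


class PDNet:
    """Extractor + classifier head with masked or gated conditioning."""

    def __init__(self, cfg: ExtractorConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        layers = []
        in_ch = 1
        for i, (ch, k, _stride) in enumerate(cfg.conv_specs):
            layers.append(nn.Conv3d(in_ch, ch, k, rng, name=f"conv{i}"))
            if cfg.use_norm:
                layers.append(nn.BatchNorm3d(ch, name=f"bn{i}"))
            layers.append(nn.ReLU())
            in_ch = ch
        self.extractor = nn.Sequential(*layers)
        self.n_features = in_ch
        head_layers = []
        if cfg.head_norm:
            head_layers.append(nn.BatchNorm1d(in_ch, name="bn_pool"))
        head_layers += [
            nn.Linear(in_ch, cfg.head_hidden, rng, name="fc0"),
            _ReLU1d(),
            nn.Linear(cfg.head_hidden, 2, rng, name="fc1"),
        ]
        self.head = nn.Sequential(*head_layers)

    def params(self) -> list[nn.Param]:
        return self.extractor.params() + self.head.params()

    # -- forward paths -----------------------------------------------------
    def feature_maps(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Extractor activations for a batch (N, 1, D, H, W)."""
        return self.extractor.forward(x, train=train)

    def logits_from_pooled(self, pooled: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(pooled, train=train)


class _ReLU1d(nn.ReLU):
    pass


def _as_batch(rois: np.ndarray) -> np.ndarray:
    rois = np.asarray(rois, dtype=np.float64)
    if rois.ndim == 3:
        rois = rois[None]
    return rois[:, None]  # (N, 1, D, H, W)


def gated_pool(feature_maps: np.ndarray, gate: np.ndarray,
               normalization: str = "weighted-average") -> np.ndarray:
    """Pool extractor feature maps through a spatial gate (one scalar per
    channel).  See :func:`nigrastab.nn.gated_pool_forward` for the two
    normalizations (in-gate weighted average vs global mean of gated maps).
    """
    fm = feature_maps if feature_maps.ndim == 5 else feature_maps[None]
    g = gate if gate.ndim == 4 else gate[None]
    out = nn.gated_pool_forward(fm, g, normalization)
    return out if feature_maps.ndim == 5 else out[0]


def masked_forward(roi_volume: np.ndarray, roi_mask: np.ndarray, model: PDNet,
                   train: bool = False) -> np.ndarray:
    """Zero-background path: input = volume x mask -> extractor -> GAP -> head.

    Returns P(PD) per subject.
    """
    x = _as_batch(roi_volume) * _as_batch(roi_mask)
    fm = model.feature_maps(x, train=train)
    pooled = nn.global_average_pool(fm)
    logits = model.logits_from_pooled(pooled, train=train)
    scores = nn.softmax(logits)[:, 1]
    return scores if np.ndim(roi_volume) == 4 else scores[0]


def gated_forward(roi_volume: np.ndarray, gate: np.ndarray, model: PDNet,
                  normalization: str = "weighted-average", train: bool = False) -> np.ndarray:
    """Gated path: extractor on the un-zeroed ROI, gate applied at pooling."""
    x = _as_batch(roi_volume)
    g = gate if gate.ndim == 4 else gate[None]
    fm = model.feature_maps(x, train=train)
    pooled = nn.gated_pool_forward(fm, g, normalization)
    logits = model.logits_from_pooled(pooled, train=train)
    scores = nn.softmax(logits)[:, 1]
    return scores if np.ndim(roi_volume) == 4 else scores[0]


@dataclass
class TrainedClassifier:
    model: PDNet
    mode: Mode
    normalization: str
    log: dict

    def predict(self, rois: np.ndarray, gates: np.ndarray) -> np.ndarray:
        if self.mode == "masked":
            return masked_forward(rois, gates, self.model, train=False)
        return gated_forward(rois, gates, self.model, self.normalization, train=False)


def _accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    return float(((scores >= 0.5).astype(int) == y).mean())


def train_classifier(
    rois: np.ndarray,
    gates: np.ndarray,
    y: np.ndarray,
    mode: Mode = "masked",
    cfg: ExtractorConfig | None = None,
    train_cfg: TrainConfig | None = None,
    normalization: str = "weighted-average",
    val_rois: np.ndarray | None = None,
    val_gates: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> TrainedClassifier:
    """Train a PDNet on pre-cropped, z-normalized ROIs.

    ``rois``/``gates`` are (N, D, H, W) stacks; ``y`` is 0/1 (1 = PD).
    Cross-entropy objective, Adam, fixed-seed initialization and batch
    order; if a validation set is given, the epoch with the best
    validation accuracy is kept (early selection).
    """
    cfg = cfg or ExtractorConfig()
    tc = train_cfg or TrainConfig()
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise ValueError("training split must contain both classes")
    model = PDNet(cfg, seed=tc.seed)
    opt = nn.Adam(model.params(), lr=tc.lr, weight_decay=tc.weight_decay)
    ce = nn.SoftmaxCrossEntropy()
    rng = np.random.default_rng(tc.seed + 1)
    n = len(y)
    history = []
    best = (-1.0, None, None)
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            bidx = order[start : start + tc.batch_size]
            if len(bidx) < 2:
                continue  # batch norm needs more than one sample
            rb, gb = rois[bidx], gates[bidx]
            if tc.flip_augment:
                # random axis flips; phantoms (and the bilateral midbrain)
                # carry no diagnostic left/right or up/down polarity
                flips = tuple(int(ax) + 1 for ax in range(3) if rng.random() < 0.5)
                if flips:
                    rb = np.flip(rb, axis=flips)
                    gb = np.flip(gb, axis=flips)
            if tc.shift_augment:
                # small random translations decouple the decision from the
                # exact ROI placement (which varies with the label source)
                shift = rng.integers(-tc.shift_augment, tc.shift_augment + 1, size=3)
                if np.any(shift):
                    rb = np.roll(rb, shift, axis=(1, 2, 3))
                    gb = np.roll(gb, shift, axis=(1, 2, 3))
            xb = _as_batch(rb)
            if mode == "masked":
                fm = model.feature_maps(xb * gb[:, None], train=True)
                pooled = nn.global_average_pool(fm)
            else:
                fm = model.feature_maps(xb, train=True)
                pooled = nn.gated_pool_forward(fm, gb, normalization)
            logits = model.logits_from_pooled(pooled, train=True)
            loss = ce.forward(logits, y[bidx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss})")
            losses.append(loss)
            opt.zero_grad()
            gl = ce.backward()
            gp = model.head.backward(gl)
            if mode == "masked":
                dfm = gp[:, :, None, None, None] * np.ones_like(fm) / np.prod(fm.shape[2:])
            else:
                dfm, _ = nn.gated_pool_backward(gp, fm, gb[:, None], normalization)
            model.extractor.backward(dfm)
            opt.step()
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_rois is not None:
            clf = TrainedClassifier(model, mode, normalization, {})
            val_acc = _accuracy(clf.predict(val_rois, val_gates), val_y)
            rec["val_accuracy"] = val_acc
            if val_acc > best[0]:
                bns = [l for l in model.extractor.layers + model.head.layers
                       if isinstance(l, (nn.BatchNorm3d, nn.BatchNorm1d))]
                best = (val_acc, [p.v.copy() for p in model.params()],
                        [(bn.running_mean.copy(), bn.running_var.copy()) for bn in bns])
        history.append(rec)
    if val_rois is not None and best[1] is not None:
        for p, v in zip(model.params(), best[1]):
            p.v[...] = v
        bns = [l for l in model.extractor.layers + model.head.layers
               if isinstance(l, (nn.BatchNorm3d, nn.BatchNorm1d))]
        for bn, (rm, rv) in zip(bns, best[2]):
            bn.running_mean, bn.running_var = rm, rv
    log = {"mode": mode, "normalization": normalization, "config": repr(cfg),
           "train_config": repr(tc), "history": history}
    return TrainedClassifier(model, mode, normalization, log)
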