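"""Coarse-to-fine SN segmentation network (SN2) and the joint
segmentation-classification model.

SN2 keeps the full spatial resolution everywhere (no pooling: the target
nucleus is tiny, and downsampling hurts contour precision) and uses
densely connected convolution blocks instead of residual ones.  Two
parallel trunks form the coarse stage: one predicts an initial SN
probability map, the other regresses the signed distance to the SN
boundary (negative inside); their outputs are concatenated channel-wise
and fused by further convolution, followed by a softmax, into the fine
segmentation.

The joint model feeds the fine probability map p through the
piecewise-linear gate

    delta(p) = 0            for p <= 0.4
             = 5 p - 2      for 0.4 < p <= 0.6
             = 1            for p > 0.6

and pools the classifier extractor's feature maps as
``feature_vector = mean(delta(p) * feature_map)``, so the diagnosis needs
no external label at inference time and gradients flow end to end
(delta is differentiable almost everywhere).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .grids import BinaryMask
from .metrics import dice_coefficient, signed_distance
from .pdnet import ExtractorConfig, PDNet, TrainConfig, _as_batch

__all__ = [
    "GateParams",
    "delta_gate",
    "delta_gate_deriv",
    "Sn2Config",
    "SN2",
    "train_sn2",
    "JointModel",
    "joint_forward",
    "train_joint",
]

log = logging.getLogger(__name__)

#: signed-distance regression targets are clipped to this range (mm) and
#: scaled to [-1, 1]
DIST_CLIP_MM = 10.0


@dataclass(frozen=True)
class GateParams:
    """Constants of the piecewise-linear probability gate."""

    t_hi: float = 0.6
    t_lo: float = 0.4
    slope: float = 5.0
    intercept: float = -2.0

    def __post_init__(self) -> None:
        if abs(self.slope * self.t_lo + self.intercept) > 1e-9:
            raise ValueError("gate must vanish at t_lo (slope*t_lo + intercept = 0)")
        if abs(self.slope * self.t_hi + self.intercept - 1.0) > 1e-9:
            raise ValueError("gate must reach 1 at t_hi (slope*t_hi + intercept = 1)")


def delta_gate(p: np.ndarray, params: GateParams = GateParams()) -> np.ndarray:
    """delta(p): 0 below t_lo, linear between, 1 above t_hi; continuous."""
    p = np.asarray(p, dtype=np.float64)
    mid = params.slope * p + params.intercept
    return np.where(p > params.t_hi, 1.0, np.where(p > params.t_lo, mid, 0.0))


def delta_gate_deriv(p: np.ndarray, params: GateParams = GateParams()) -> np.ndarray:
    """d delta/dp (defined a.e.; slope inside the ramp, 0 elsewhere)."""
    p = np.asarray(p, dtype=np.float64)
    return np.where((p > params.t_lo) & (p <= params.t_hi), params.slope, 0.0)


@dataclass(frozen=True)
class Sn2Config:
    """Topology and loss weights of the segmentation network.

    The trunk contains no spatial downsampling; both heads share the
    input grid resolution.
    """

    dense_depth: int = 3
    growth: int = 6
    kernel: int = 3
    fusion_channels: int = 8
    fusion_kernel: int = 3
    w_seg: float = 1.0
    w_dist: float = 0.5
    w_cls: float = 1.0

    def __post_init__(self) -> None:
        if self.dense_depth < 1 or self.growth < 1:
            raise ValueError("dense_depth and growth must be >= 1")


class DenseBlock:
    """Densely connected conv stack: layer i consumes the channel
    concatenation of the input and all previous layer outputs."""

    def __init__(self, in_ch: int, depth: int, growth: int, kernel: int,
                 rng: np.random.Generator, name: str):
        self.convs, self.bns, self.relus = [], [], []
        self.channel_plan = [in_ch]
        ch = in_ch
        for i in range(depth):
            self.convs.append(nn.Conv3d(ch, growth, kernel, rng, name=f"{name}.conv{i}"))
            self.bns.append(nn.BatchNorm3d(growth, name=f"{name}.bn{i}"))
            self.relus.append(nn.ReLU())
            self.channel_plan.append(growth)
            ch += growth
        self.out_channels = ch

    def params(self) -> list[nn.Param]:
        out = []
        for c, b in zip(self.convs, self.bns):
            out.extend(c.params())
            out.extend(b.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        feats = [x]
        for conv, bn, relu in zip(self.convs, self.bns, self.relus):
            inp = np.concatenate(feats, axis=1)
            y = relu.forward(bn.forward(conv.forward(inp, train), train), train)
            feats.append(y)
        if train:
            self._shapes = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        splits = np.cumsum(self._shapes)[:-1]
        grads = list(np.split(grad, splits, axis=1))
        for i in reversed(range(len(self.convs))):
            g = grads[i + 1]
            g = self.convs[i].backward(self.bns[i].backward(self.relus[i].backward(g)))
            # distribute onto the concatenated inputs (feats[0..i])
            in_splits = np.cumsum(self._shapes[: i + 1])[:-1]
            for j, gj in enumerate(np.split(g, in_splits, axis=1)):
                grads[j] = grads[j] + gj
        return grads[0]


def _softmax_ch(logits: np.ndarray) -> np.ndarray:
    return nn.softmax(logits, axis=1)


def _softmax_ch_backward(p: np.ndarray, grad: np.ndarray) -> np.ndarray:
    # per-voxel softmax Jacobian along the channel axis
    dot = (grad * p).sum(axis=1, keepdims=True)
    return p * (grad - dot)


class SN2:
    """Two parallel dense trunks (probability + signed distance), channel
    concatenation, fusion convolution, softmax fine segmentation."""

    def __init__(self, cfg: Sn2Config = Sn2Config(), seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.seg_trunk = DenseBlock(1, cfg.dense_depth, cfg.growth, cfg.kernel, rng, "seg")
        self.seg_head = nn.Conv3d(self.seg_trunk.out_channels, 2, 1, rng, name="seg_head")
        self.dist_trunk = DenseBlock(1, cfg.dense_depth, cfg.growth, cfg.kernel, rng, "dist")
        self.dist_head = nn.Conv3d(self.dist_trunk.out_channels, 1, 1, rng, name="dist_head")
        self.fusion = nn.Sequential(
            nn.Conv3d(3, cfg.fusion_channels, cfg.fusion_kernel, rng, name="fusion0"),
            nn.BatchNorm3d(cfg.fusion_channels, name="fusion_bn"),
            nn.ReLU(),
            nn.Conv3d(cfg.fusion_channels, 2, 1, rng, name="fusion1"),
        )
        self.n_params = sum(p.v.size for p in self.params())

    def params(self) -> list[nn.Param]:
        return (self.seg_trunk.params() + self.seg_head.params()
                + self.dist_trunk.params() + self.dist_head.params()
                + self.fusion.params())

    def forward(self, x: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        """x: (N, 1, D, H, W) z-normalized ROI.  Returns initial probability,
        scaled distance prediction, fine logits and fine probability — all
        on the input grid (no downsampling anywhere)."""
        f_seg = self.seg_trunk.forward(x, train)
        init_logits = self.seg_head.forward(f_seg, train)
        init_prob = _softmax_ch(init_logits)
        f_dist = self.dist_trunk.forward(x, train)
        dist = self.dist_head.forward(f_dist, train)
        fused_in = np.concatenate([init_prob, dist], axis=1)
        fine_logits = self.fusion.forward(fused_in, train)
        fine_prob = _softmax_ch(fine_logits)
        if train:
            self._cache = (init_prob, fused_in)
        return {
            "initial_prob": init_prob,
            "distance": dist,
            "fine_logits": fine_logits,
            "fine_prob": fine_prob,
        }

    def backward(self, d_fine_logits: np.ndarray, d_dist: np.ndarray | None = None) -> None:
        """Backprop from fine-segmentation logits (and optionally the
        distance head's own loss gradient)."""
        init_prob, _ = self._cache
        d_fused = self.fusion.backward(d_fine_logits)
        d_init_prob, d_dist_f = d_fused[:, :2], d_fused[:, 2:]
        if d_dist is not None:
            d_dist_f = d_dist_f + d_dist
        d_init_logits = _softmax_ch_backward(init_prob, d_init_prob)
        self.seg_trunk.backward(self.seg_head.backward(d_init_logits))
        self.dist_trunk.backward(self.dist_head.backward(d_dist_f))

    def predict_prob(self, roi: np.ndarray) -> np.ndarray:
        """Fine SN probability map for one z-normalized ROI (D, H, W)."""
        out = self.forward(_as_batch(roi), train=False)
        return out["fine_prob"][0, 1]


def build_sn2(cfg: Sn2Config = Sn2Config(), seed: int = 0) -> SN2:
    model = SN2(cfg, seed)
    log.info("SN2 built: %d parameters", model.n_params)
    return model


# ---------------------------------------------------------------------------
# losses


def _soft_dice_and_grad(p1: np.ndarray, target: np.ndarray, eps: float = 1e-6):
    """Soft Dice loss (1 - Dice) on the foreground probability channel and
    its gradient, per batch sample."""
    axes = (1, 2, 3)
    inter = (p1 * target).sum(axis=axes)
    denom = p1.sum(axis=axes) + target.sum(axis=axes) + eps
    dice = (2 * inter + eps) / denom
    loss = float((1 - dice).mean())
    n = p1.shape[0]
    grad = -(2 * target * denom[:, None, None, None]
             - (2 * inter + eps)[:, None, None, None]) / denom[:, None, None, None] ** 2 / n
    return loss, grad


def _seg_loss_and_grad(fine_logits, fine_prob, target):
    """w-less segmentation loss: soft Dice + voxelwise cross-entropy on the
    fine segmentation; returns (loss, d_loss/d_fine_logits)."""
    n, _, d, h, w = fine_logits.shape
    nv = n * d * h * w
    p1 = fine_prob[:, 1]
    dice_loss, d_dice_p1 = _soft_dice_and_grad(p1, target)
    # route the dice gradient through the softmax
    d_prob = np.zeros_like(fine_prob)
    d_prob[:, 1] = d_dice_p1
    g_dice = _softmax_ch_backward(fine_prob, d_prob)
    # cross-entropy on logits (softmax grad in closed form)
    t1 = target
    ce = float(-(t1 * np.log(np.clip(fine_prob[:, 1], 1e-12, None))
                 + (1 - t1) * np.log(np.clip(fine_prob[:, 0], 1e-12, None))).mean())
    onehot = np.stack([1 - t1, t1], axis=1)
    g_ce = (fine_prob - onehot) / nv
    return dice_loss + ce, g_dice + g_ce


def _dist_targets(masks: np.ndarray, spacing) -> np.ndarray:
    """Scaled signed-distance targets in [-1, 1] from binary ROI masks."""
    out = np.empty(masks.shape, dtype=np.float64)
    for i, m in enumerate(masks):
        if m.any() and not m.all():
            sd = signed_distance(BinaryMask(m.astype(np.uint8), spacing)).values
        else:  # degenerate ROI: flat far-outside target
            sd = np.full(m.shape, DIST_CLIP_MM)
        out[i] = np.clip(sd, -DIST_CLIP_MM, DIST_CLIP_MM) / DIST_CLIP_MM
    return out


def train_sn2(
    rois: np.ndarray,
    masks: np.ndarray,
    spacing,
    cfg: Sn2Config = Sn2Config(),
    seed: int = 0,
    epochs: int = 12,
    batch_size: int = 6,
    lr: float = 3e-3,
    val_rois: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
    stop_at_val_dice: float | None = None,
) -> tuple[SN2, dict]:
    """Train the segmentation network on pre-cropped, intensity-scaled ROIs.

    Loss: ``w_seg * (soft Dice + cross-entropy on the fine segmentation)
    + w_dist * L1`` on the scaled signed-distance head.  Returns the model
    and a log with per-epoch losses and (if a validation set is given)
    per-epoch mean validation Dice.

    ``stop_at_val_dice`` halts training at the first epoch whose validation
    Dice reaches the value — used to produce an automatic labeler of
    controlled quality (phantom nuclei are much easier to segment than
    real midbrain anatomy, so an unconstrained model would be nearly
    perfect and could not stand in for a realistic automatic label source).
    """
    model = SN2(cfg, seed)
    opt = nn.Adam(model.params(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    dist_t = _dist_targets(masks, spacing)
    n = len(rois)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            bidx = order[start : start + batch_size]
            if len(bidx) < 2:
                continue
            xb = _as_batch(rois[bidx])
            tb = masks[bidx].astype(np.float64)
            db = dist_t[bidx][:, None]
            out = model.forward(xb, train=True)
            seg_loss, g_logits = _seg_loss_and_grad(out["fine_logits"], out["fine_prob"], tb)
            resid = out["distance"] - db
            dist_loss = float(np.abs(resid).mean())
            g_dist = np.sign(resid) / resid.size
            loss = cfg.w_seg * seg_loss + cfg.w_dist * dist_loss
            if not np.isfinite(loss):
                raise RuntimeError(f"SN2 training diverged at epoch {epoch}")
            losses.append(loss)
            opt.zero_grad()
            model.backward(cfg.w_seg * g_logits, cfg.w_dist * g_dist)
            opt.step()
        rec = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_rois is not None:
            rec["val_dice"] = float(np.mean([
                dice_coefficient(model.predict_prob(r) >= 0.5, m.astype(bool))
                for r, m in zip(val_rois, val_masks)
            ]))
        history.append(rec)
        if (stop_at_val_dice is not None and "val_dice" in rec
                and rec["val_dice"] >= stop_at_val_dice):
            break
    return model, {"history": history, "n_params": model.n_params, "config": repr(cfg)}


# ---------------------------------------------------------------------------
# joint model


@dataclass
class JointModel:
    """End-to-end diagnosis model: SN2 fine probability -> delta gate ->
    gated pooling of the classifier extractor -> head.

    ``normalization`` selects between the in-gate weighted average
    (default; the same normalization the binary gated classifier uses,
    so the four-way train/test-label comparison differs only in where
    the gate comes from) and the literal global mean of the gated maps.
    """

    sn2: SN2
    classifier: PDNet
    gate_params: GateParams = field(default_factory=GateParams)
    normalization: str = "weighted-average"

    def params(self) -> list[nn.Param]:
        return self.sn2.params() + self.classifier.params()


def _joint_pool(fm: np.ndarray, gate: np.ndarray, normalization: str):
    """Gated pooling with a safe zero-gate path (pooled vector = 0)."""
    g = gate[:, None]
    if normalization == "global-mean":
        return (fm * g).mean(axis=(2, 3, 4))
    if normalization == "weighted-average":
        denom = np.clip(g.sum(axis=(2, 3, 4)), 1e-12, None)
        return (fm * g).sum(axis=(2, 3, 4)) / denom
    raise ValueError(f"unknown normalization {normalization!r}")


def _joint_pool_backward(grad, fm, gate, normalization):
    g = gate[:, None]
    gexp = grad[:, :, None, None, None]
    if normalization == "global-mean":
        m = np.prod(fm.shape[2:])
        dfm = gexp * g / m
        dgate = (gexp * fm / m).sum(axis=1)
    else:
        denom = np.clip(g.sum(axis=(2, 3, 4)), 1e-12, None)[:, :, None, None, None]
        dfm = gexp * g / denom
        pooled = (fm * g).sum(axis=(2, 3, 4), keepdims=True) / denom
        dgate = (gexp * (fm - pooled) / denom).sum(axis=1)
    return dfm, dgate


def joint_forward(roi_volume: np.ndarray, model: JointModel, train: bool = False):
    """Mask-free inference: returns (fine probability map(s), P(PD) score(s)).

    If no voxel passes the lower gate threshold, the pooled feature vector
    is exactly zero and the head's output on the zero vector is returned
    (flagged in the log).
    """
    single = np.ndim(roi_volume) == 3
    x = _as_batch(roi_volume)
    out = model.sn2.forward(x, train=train)
    p = out["fine_prob"][:, 1]
    gate = delta_gate(p, model.gate_params)
    if np.any(gate.sum(axis=(1, 2, 3)) == 0):
        log.warning("delta gate identically zero: score falls back to the zero feature vector")
    fm = model.classifier.feature_maps(x, train=train)
    pooled = _joint_pool(fm, gate, model.normalization)
    logits = model.classifier.logits_from_pooled(pooled, train=train)
    scores = nn.softmax(logits)[:, 1]
    if train:
        model._cache = (out, p, gate, fm, pooled, logits)
    if single:
        return p[0], float(scores[0])
    return p, scores


def train_joint(
    rois: np.ndarray,
    masks: np.ndarray,
    y: np.ndarray,
    spacing,
    sn2_cfg: Sn2Config = Sn2Config(),
    ext_cfg: ExtractorConfig | None = None,
    train_cfg: TrainConfig | None = None,
    warmstart_sn2: SN2 | None = None,
    warmstart_classifier: PDNet | None = None,
    normalization: str = "weighted-average",
    warmup_epochs: int = 4,
    val_rois: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> tuple[JointModel, dict]:
    """End-to-end training of the unified model.

    Combined loss ``w_seg * seg + w_dist * dist + w_cls * class``;
    reference masks supervise the segmentation heads during training only,
    and gradients of the classification term flow through delta(p) into
    SN2 (piecewise-linear, differentiable a.e.).  The SN2 trunk is
    warm-started either from ``warmstart_sn2`` or from ``warmup_epochs``
    of segmentation-only training (set 0 for end-to-end from scratch).
    """
    ext_cfg = ext_cfg or ExtractorConfig()
    tc = train_cfg or TrainConfig()
    y = np.asarray(y, dtype=int)
    if warmstart_sn2 is not None:
        sn2 = copy.deepcopy(warmstart_sn2)  # never mutate a shared warm start
    else:
        sn2, _ = train_sn2(rois, masks, spacing, sn2_cfg, seed=tc.seed,
                           epochs=warmup_epochs, lr=tc.lr)
    if warmstart_classifier is not None:
        classifier = copy.deepcopy(warmstart_classifier)
    else:
        classifier = PDNet(ext_cfg, seed=tc.seed)
    model = JointModel(sn2, classifier, normalization=normalization)
    # recalibrate batch-norm running statistics for this model's pooling
    # scale (a warm-started head has stats from a different gating mode)
    bns = [l for l in classifier.extractor.layers + classifier.head.layers
           if isinstance(l, (nn.BatchNorm3d, nn.BatchNorm1d))]
    old_mom = [b.momentum for b in bns]
    for b in bns:
        b.momentum = 0.5
    for _ in range(3):
        joint_forward(rois, model, train=True)
    for b, m0 in zip(bns, old_mom):
        b.momentum = m0
    opt = nn.Adam(model.params(), lr=tc.lr, weight_decay=tc.weight_decay)
    ce = nn.SoftmaxCrossEntropy()
    rng = np.random.default_rng(tc.seed + 2)
    dist_t = _dist_targets(masks, spacing)
    n = len(rois)
    history = []
    best = (-1.0, None, None)
    cfg = sn2_cfg
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        terms = []
        for start in range(0, n, tc.batch_size):
            bidx = order[start : start + tc.batch_size]
            if len(bidx) < 2:
                continue
            xb = rois[bidx]
            tb = masks[bidx].astype(np.float64)
            db = dist_t[bidx][:, None]
            if tc.flip_augment:
                flips = tuple(int(ax) for ax in range(3) if rng.random() < 0.5)
                if flips:
                    ax = tuple(a + 1 for a in flips)
                    xb = np.flip(xb, axis=ax)
                    tb = np.flip(tb, axis=ax)
                    db = np.flip(db, axis=tuple(a + 2 for a in flips))
            _, scores = joint_forward(xb, model, train=True)
            out, p, gate, fm, pooled, logits = model._cache
            seg_loss, g_logits_seg = _seg_loss_and_grad(out["fine_logits"], out["fine_prob"], tb)
            resid = out["distance"] - db
            dist_loss = float(np.abs(resid).mean())
            cls_loss = ce.forward(logits, y[bidx])
            loss = cfg.w_seg * seg_loss + cfg.w_dist * dist_loss + cfg.w_cls * cls_loss
            if not np.isfinite(loss):
                raise RuntimeError(f"joint training diverged at epoch {epoch}")
            terms.append((seg_loss, dist_loss, cls_loss))
            opt.zero_grad()
            # classification branch
            g_head = ce.backward() * cfg.w_cls
            g_pooled = model.classifier.head.backward(g_head)
            dfm, dgate = _joint_pool_backward(g_pooled, fm, gate, model.normalization)
            model.classifier.extractor.backward(dfm)
            # gate gradient -> fine prob channel 1 -> fine logits
            dp1 = dgate * delta_gate_deriv(p, model.gate_params)
            d_prob = np.zeros_like(out["fine_prob"])
            d_prob[:, 1] = dp1
            g_logits_gate = _softmax_ch_backward(out["fine_prob"], d_prob)
            g_dist = cfg.w_dist * np.sign(resid) / resid.size
            model.sn2.backward(cfg.w_seg * g_logits_seg + g_logits_gate, g_dist)
            opt.step()
        seg_m, dist_m, cls_m = (float(np.mean([t[i] for t in terms])) for i in range(3))
        rec = {"epoch": epoch, "seg_loss": seg_m, "dist_loss": dist_m, "cls_loss": cls_m}
        if val_rois is not None:
            _, vs = joint_forward(val_rois, model, train=False)
            vacc = float(((vs >= 0.5).astype(int) == val_y).mean())
            rec["val_accuracy"] = vacc
            if vacc > best[0]:
                best = (vacc, [pp.v.copy() for pp in model.params()],
                        [(b.running_mean.copy(), b.running_var.copy()) for b in _all_bns(model)])
        history.append(rec)
    if val_rois is not None and best[1] is not None:
        for pp, v in zip(model.params(), best[1]):
            pp.v[...] = v
        for b, (rm, rv) in zip(_all_bns(model), best[2]):
            b.running_mean, b.running_var = rm, rv
    return model, {"history": history}


def _all_bns(model: JointModel):
    layers = (model.classifier.extractor.layers + model.classifier.head.layers
              + model.sn2.fusion.layers)
    bns = [l for l in layers if isinstance(l, (nn.BatchNorm3d, nn.BatchNorm1d))]
    for trunk in (model.sn2.seg_trunk, model.sn2.dist_trunk):
        bns.extend(trunk.bns)
    return bns
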