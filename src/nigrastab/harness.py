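"""Experiment orchestration: the three stability experiments at desk scale.

1. **Population-level stability** — train a classifier on the reference
   labels, test it against every label set in a Dice-graded series, and
   tabulate the classification panel per Dice level (accuracy trend).
2. **Intrasubject consistency** — pool test predictions across
   cross-validation permutations and compute the pairwise classification
   consistency index (CCI) matrix over label sources, for the masked and
   the gated model.
3. **Joint-model comparison** — four configurations on identical splits:
   gated model trained/tested on reference labels; trained on reference,
   tested on automatic (segmenter-produced) labels; trained and tested on
   automatic labels; and the end-to-end joint model that needs no label
   at test time.

Splits follow a stratified nested cross-validation plan (outer test
folds, inner validation split used for epoch selection only), repeated
over permutations; every stochastic step derives its seed from one
master seed.

The default ``DeskScaleConfig`` is sized for single-CPU runs: 50-subject
cohorts on small grids with compact networks.  The study-shaped numbers
(cohort 87+53, sevenfold splits of 100/20/20, 50 permutations) are
configuration values, not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .grids import BinaryMask
from .labels import DEFAULT_TARGETS, LabelSeries, make_label_series
from .metrics import (
    PredictionTable,
    cci_matrix,
    classification_panel,
    paired_comparison,
)
from .pdnet import (
    ExtractorConfig,
    TrainConfig,
    center_roi,
    crop_like,
    crop_roi,
    normalize_roi,
    train_classifier,
)
from .phantom import Cohort, PhantomParams, generate_cohort
from .radiomics import cohort_feature_matrix, icc_screen, predict_scores, rfe_train
from .sn2 import SN2, Sn2Config, joint_forward, train_joint, train_sn2

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "DeskScaleConfig",
    "prepare_inputs",
    "CohortInputs",
    "run_population_stability",
    "run_cci_experiment",
    "train_auto_segmenter",
    "run_joint_comparison",
    "render_reports",
    "stability_report",
    "build_desk_study",
    "run_full_study",
    "StudyResults",
]

ModelKind = Literal["radiomics-lr", "pdnet-masked", "pdnet-gated"]


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass
class CVPlan:
    """Stratified nested CV assignments: ``splits[permutation][fold]`` is a
    (train, val, test) triple of subject-index arrays."""

    n_subjects: int
    folds: int
    n_permutations: int
    seed: int
    splits: list[list[tuple[np.ndarray, np.ndarray, np.ndarray]]]

    def iter_splits(self):
        for perm, folds in enumerate(self.splits):
            for fold, (tr, va, te) in enumerate(folds):
                yield perm, fold, tr, va, te


def make_cv_plan(
    diagnoses: np.ndarray,
    folds: int = 7,
    proportions: tuple[float, float, float] = (100 / 140, 20 / 140, 20 / 140),
    n_permutations: int = 1,
    seed: int = 0,
) -> CVPlan:
    """Build a deterministic stratified nested cross-validation plan.

    Per permutation, each class is shuffled and dealt into ``folds`` test
    folds; for each fold the remaining subjects are split into train and
    validation by ``proportions`` (test size is set by the fold, so only
    the train:val ratio of the proportions matters there).  Splits are
    disjoint and exhaustive; every split contains both classes.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    y = np.asarray(diagnoses)
    n = len(y)
    classes = np.unique(y)
    counts = {c: int((y == c).sum()) for c in classes}
    if any(v < folds for v in counts.values()):
        raise ValueError(f"class too small to stratify into {folds} folds: {counts}")
    rng = np.random.default_rng(seed)
    val_frac_of_rest = proportions[1] / (proportions[0] + proportions[1])
    splits = []
    for _ in range(n_permutations):
        fold_members: list[list[int]] = [[] for _ in range(folds)]
        for c in classes:
            idx = rng.permutation(np.flatnonzero(y == c))
            for i, s in enumerate(idx):
                fold_members[i % folds].append(int(s))
        perm_splits = []
        for f in range(folds):
            test = np.sort(np.array(fold_members[f]))
            rest = np.array(sorted(set(range(n)) - set(test)))
            # stratified train/val split of the rest
            val_parts, train_parts = [], []
            for c in classes:
                rc = rng.permutation(rest[y[rest] == c])
                n_val = max(1, int(round(len(rc) * val_frac_of_rest)))
                val_parts.append(rc[:n_val])
                train_parts.append(rc[n_val:])
            val = np.sort(np.concatenate(val_parts))
            train = np.sort(np.concatenate(train_parts))
            for name, part in (("train", train), ("val", val), ("test", test)):
                if len(np.unique(y[part])) < len(classes):
                    raise ValueError(f"{name} split lost a class (n too small)")
            perm_splits.append((train, val, test))
        splits.append(perm_splits)
    return CVPlan(n, folds, n_permutations, seed, splits)


# ---------------------------------------------------------------------------
# desk-scale configuration


def _desk_phantom() -> PhantomParams:
    return PhantomParams(
        grid_shape=(24, 24, 16),
        spacing=(1.0, 1.0, 1.0),
        nucleus_radius_range=(2.4, 2.9),
        bilateral_offset_frac=0.15,
    )


@dataclass
class DeskScaleConfig:
    """Single-CPU experiment settings.

    Cohort size keeps the study's ~62% disease prevalence; grids, ROIs
    and network widths are the smallest that preserve the phenomena
    (compact bright nuclei, sharp rims, label-dependent inputs).
    """

    n_pd: int = 31
    n_hc: int = 19
    phantom: PhantomParams = field(default_factory=_desk_phantom)
    roi_shape: tuple[int, int, int] = (18, 18, 10)
    margin: int = 2
    targets: tuple[float, ...] = DEFAULT_TARGETS
    dice_tol: float = 0.005
    alpha_max: float = 15.0  # peak field magnitude can sit far from the nuclei
    folds: int = 7
    n_permutations: int = 1
    extractor: ExtractorConfig = None  # type: ignore[assignment]
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=20))
    sn2: Sn2Config = field(default_factory=Sn2Config)
    sn2_epochs: int = 16
    sn2_lr: float = 3e-3
    joint_epochs: int = 12
    auto_label_dice: float = 0.87
    rfe_n_final: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extractor is None:
            self.extractor = ExtractorConfig(
                input_roi_shape=self.roi_shape,
                conv_specs=((6, 5, 1), (8, 3, 1)),
                use_norm=False,
                head_norm=True,
                head_hidden=8,
                margin=self.margin,
            )


# ---------------------------------------------------------------------------
# input preparation


@dataclass
class CohortInputs:
    """Pre-cropped network inputs for every label source.

    ``rois[target]`` / ``gates[target]`` are (N, D, H, W) stacks cropped
    around each subject's mask from that label source; ``center_rois`` /
    ``center_masks`` are the mask-free grid-center crops the joint model
    uses (reference masks cropped alongside for training supervision).
    """

    subject_ids: list[str]
    y: np.ndarray  # 1 = PD
    spacing: np.ndarray
    rois: dict[float, np.ndarray]
    gates: dict[float, np.ndarray]
    center_rois: np.ndarray
    center_masks: np.ndarray

    @property
    def true_class(self) -> np.ndarray:
        return np.where(self.y == 1, "PD", "HC")


def _crop_source(cohort: Cohort, masks: dict[str, BinaryMask], roi_shape, margin):
    rois, gates = [], []
    for s in cohort:
        v, m, _ = crop_roi(s.volume, masks[s.subject_id], margin=margin, roi_shape=roi_shape)
        rois.append(normalize_roi(v))
        gates.append(m)
    return np.array(rois), np.array(gates)


def prepare_inputs(cohort: Cohort, series: LabelSeries, cfg: DeskScaleConfig) -> CohortInputs:
    rois, gates = {}, {}
    for level in series.levels:
        r, g = _crop_source(cohort, level.masks, cfg.roi_shape, cfg.margin)
        rois[level.target_dice] = r
        gates[level.target_dice] = g
    c_rois, c_masks = [], []
    for s in cohort:
        v, geom = center_roi(s.volume, cfg.roi_shape)
        c_rois.append(normalize_roi(v))
        c_masks.append(crop_like(s.mask.values, geom))
    y = np.array([1 if s.diagnosis == "PD" else 0 for s in cohort])
    return CohortInputs(
        [s.subject_id for s in cohort],
        y,
        np.asarray(cohort.subjects[0].volume.spacing),
        rois,
        gates,
        np.array(c_rois),
        np.array(c_masks),
    )


# ---------------------------------------------------------------------------
# experiment 1: population-level stability


def _rows_from_scores(data, idx, level, scores, perm, fold):
    return [
        {
            "subject_id": data.subject_ids[i],
            "label_source": level,
            "true_class": "PD" if data.y[i] == 1 else "HC",
            "predicted_class": "PD" if sc >= 0.5 else "HC",
            "score": float(sc),
            "permutation": perm,
            "fold": fold,
        }
        for i, sc in zip(idx, scores)
    ]


def _split_seed(master: int, perm: int, fold: int) -> int:
    return int(np.random.SeedSequence([master, perm, fold]).generate_state(1)[0] % (2**31))


def run_population_stability(
    cohort: Cohort,
    series: LabelSeries,
    model_kind: ModelKind,
    plan: CVPlan,
    cfg: DeskScaleConfig,
    inputs: CohortInputs | None = None,
    features: dict[float, pd.DataFrame] | None = None,
    model_sink: dict | None = None,
) -> tuple[PredictionTable, pd.DataFrame]:
    """Train on reference labels, test once per Dice level.

    Returns the full prediction table and the Table-1-style report (one
    row per Dice level; accuracy/AUC/BAC/sensitivity/specificity as mean
    and SD over the ``folds x permutations`` test splits).
    """
    targets = series.targets
    table = PredictionTable.empty()
    data = inputs if inputs is not None else _minimal_inputs(cohort)
    if model_kind == "radiomics-lr":
        if features is None:
            features = {
                lv.target_dice: cohort_feature_matrix(cohort, lv.masks) for lv in series.levels
            }
        ref = features[1.0]
        y_all = pd.Series(
            {s.subject_id: s.diagnosis for s in cohort}
        ).reindex(ref.index)
        ids = list(ref.index)
        id_of = {s.subject_id: i for i, s in enumerate(cohort)}
        for perm, fold, tr, va, te in plan.iter_splits():
            tr_full = np.concatenate([tr, va])  # LR has no epoch selection
            tr_ids = [cohort.subjects[i].subject_id for i in tr_full]
            te_ids = [cohort.subjects[i].subject_id for i in te]
            screen = icc_screen(
                ref.loc[tr_ids],
                [features[t].loc[tr_ids] for t in targets if t != 1.0],
            )
            kept = screen.kept_names or list(ref.columns)  # degenerate fallback
            model = rfe_train(ref.loc[tr_ids, kept], y_all.loc[tr_ids].values,
                              n_final=min(cfg.rfe_n_final, len(kept)))
            for t in targets:
                sc = predict_scores(model, features[t].loc[te_ids])
                table.append_rows(
                    _rows_from_scores(data, [id_of[sid] for sid in te_ids], t, sc, perm, fold)
                )
    else:
        if inputs is None:
            raise ValueError("CNN experiments need prepared CohortInputs")
        mode = "masked" if model_kind == "pdnet-masked" else "gated"
        r_ref, g_ref = inputs.rois[1.0], inputs.gates[1.0]
        for perm, fold, tr, va, te in plan.iter_splits():
            tc = replace(cfg.train, seed=_split_seed(cfg.seed, perm, fold))
            clf = train_classifier(
                r_ref[tr], g_ref[tr], inputs.y[tr], mode=mode, cfg=cfg.extractor,
                train_cfg=tc, val_rois=r_ref[va], val_gates=g_ref[va], val_y=inputs.y[va],
            )
            if model_sink is not None:
                model_sink[(perm, fold)] = clf
            for t in targets:
                sc = clf.predict(inputs.rois[t][te], inputs.gates[t][te])
                table.append_rows(_rows_from_scores(inputs, te, t, sc, perm, fold))
    report = stability_report(table, targets)
    return table, report


def _minimal_inputs(cohort: Cohort) -> CohortInputs:
    y = np.array([1 if s.diagnosis == "PD" else 0 for s in cohort])
    return CohortInputs([s.subject_id for s in cohort], y,
                        np.asarray(cohort.subjects[0].volume.spacing), {}, {},
                        np.empty(0), np.empty(0))


def stability_report(table: PredictionTable, targets) -> pd.DataFrame:
    """Per-Dice-level metric panel aggregated over test splits."""
    rows = []
    for t in targets:
        sl = table.source(t)
        panels = [
            classification_panel(g).as_dict()
            for _, g in sl.groupby(["permutation", "fold"])
        ]
        pdf = pd.DataFrame(panels)
        row = {"dice": t, "n_splits": len(panels)}
        for m in pdf.columns:
            row[f"{m}_mean"] = pdf[m].mean()
            row[f"{m}_sd"] = pdf[m].std(ddof=1) if len(pdf) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiment 2: CCI


def run_cci_experiment(
    tables: dict[str, PredictionTable], targets
) -> dict[str, pd.DataFrame]:
    """Pairwise CCI matrices from pooled test predictions (pooling across
    all permutations and folds, the testing-set construction of the
    consistency analysis)."""
    return {name: cci_matrix(tab, sources=list(targets)) for name, tab in tables.items()}


# ---------------------------------------------------------------------------
# experiment 3: joint comparison


def train_auto_segmenter(
    cohort: Cohort, inputs: CohortInputs, cfg: DeskScaleConfig, converge: bool = False
) -> tuple[SN2, dict[str, BinaryMask], float]:
    """Produce an out-of-sample automatic label for every subject.

    Two SN2 models are trained on complementary stratified halves of the
    cohort; each subject is then labeled by the model that never saw its
    reference mask, so every automatic label has genuine held-out
    quality (a deployed segmenter never trains on the case it labels).
    Unless ``converge`` is set, each training halts once held-out Dice
    reaches ``cfg.auto_label_dice``, emulating a realistic automatic
    segmentation quality rather than the near-perfect contours phantom
    nuclei would otherwise allow.

    Returns (first model, auto masks on the full grids, mean Dice of the
    automatic labels against the references).
    """
    from .metrics import dice_coefficient  # local to avoid cycle at import time

    rng = np.random.default_rng(cfg.seed + 17)
    idx_pd = rng.permutation(np.flatnonzero(inputs.y == 1))
    idx_hc = rng.permutation(np.flatnonzero(inputs.y == 0))
    half_a = np.sort(np.concatenate([idx_pd[: len(idx_pd) // 2], idx_hc[: len(idx_hc) // 2]]))
    half_b = np.sort(np.array(sorted(set(range(len(inputs.y))) - set(half_a))))
    r, m = inputs.center_rois, inputs.center_masks
    stop = None if converge else cfg.auto_label_dice
    models = {}
    for name, tr_idx, va_idx in (("a", half_a, half_b), ("b", half_b, half_a)):
        models[name], _ = train_sn2(
            r[tr_idx], m[tr_idx], inputs.spacing, cfg.sn2, seed=cfg.seed + 18,
            epochs=cfg.sn2_epochs, lr=cfg.sn2_lr,
            val_rois=r[va_idx], val_masks=m[va_idx], stop_at_val_dice=stop,
        )
    labeler_of = {int(i): models["b"] for i in half_a}
    labeler_of.update({int(i): models["a"] for i in half_b})

    dices, auto_masks = [], {}
    for i, s in enumerate(cohort):
        pred = (labeler_of[i].predict_prob(r[i]) >= 0.5).astype(np.uint8)
        if pred.sum() == 0:  # degenerate prediction: fall back to reference
            pred = m[i].astype(np.uint8)
        dices.append(dice_coefficient(pred.astype(bool), m[i] > 0))
        # place the predicted ROI mask back onto the full grid
        full = np.zeros(s.mask.shape, dtype=np.uint8)
        _, geom = center_roi(s.volume, cfg.roi_shape)
        sl_src, sl_dst = _roi_to_grid_slices(geom)
        full[sl_dst] = pred[sl_src]
        auto_masks[s.subject_id] = BinaryMask(full, s.mask.spacing, s.mask.origin)
    return models["a"], auto_masks, float(np.mean(dices))


def _roi_to_grid_slices(geom):
    src, dst = [], []
    for st, w, dim in zip(geom.start, geom.roi_shape, geom.source_shape):
        lo = max(0, st)
        hi = min(dim, st + w)
        src.append(slice(lo - st, hi - st))
        dst.append(slice(lo, hi))
    return tuple(src), tuple(dst)


def run_joint_comparison(
    cohort: Cohort,
    inputs: CohortInputs,
    auto_masks: dict[str, BinaryMask],
    sn2_warmstart: SN2,
    plan: CVPlan,
    cfg: DeskScaleConfig,
    gated_ref_models: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate the four train/test label configurations on identical splits.

    ``ref/ref``    gated model trained and tested on reference labels;
    ``ref/auto``   the same trained models, tested with automatic labels;
    ``auto/auto``  gated models trained and tested on automatic labels;
    ``joint/none`` end-to-end model, no label consumed at test time.

    Returns (per-split accuracy table, summary with paired tests against
    ``ref/auto`` — the deployment configuration the joint model replaces).
    """
    r_ref, g_ref = inputs.rois[1.0], inputs.gates[1.0]
    r_auto, g_auto = _crop_source(cohort, auto_masks, cfg.roi_shape, cfg.margin)
    rows = []
    for perm, fold, tr, va, te in plan.iter_splits():
        seed = _split_seed(cfg.seed, perm, fold)
        tc = replace(cfg.train, seed=seed)
        if gated_ref_models is not None and (perm, fold) in gated_ref_models:
            gated_ref = gated_ref_models[(perm, fold)]
        else:
            gated_ref = train_classifier(
                r_ref[tr], g_ref[tr], inputs.y[tr], mode="gated", cfg=cfg.extractor,
                train_cfg=tc, val_rois=r_ref[va], val_gates=g_ref[va], val_y=inputs.y[va],
            )
        gated_auto = train_classifier(
            r_auto[tr], g_auto[tr], inputs.y[tr], mode="gated", cfg=cfg.extractor,
            train_cfg=tc, val_rois=r_auto[va], val_gates=g_auto[va], val_y=inputs.y[va],
        )
        jm, _ = train_joint(
            inputs.center_rois[tr], inputs.center_masks[tr], inputs.y[tr], inputs.spacing,
            cfg.sn2, cfg.extractor,
            replace(cfg.train, seed=seed, epochs=cfg.joint_epochs),
            warmstart_sn2=sn2_warmstart,
            warmstart_classifier=gated_ref.model,
            val_rois=inputs.center_rois[va], val_y=inputs.y[va],
        )
        preds = {
            "ref/ref": gated_ref.predict(r_ref[te], g_ref[te]),
            "ref/auto": gated_ref.predict(r_auto[te], g_auto[te]),
            "auto/auto": gated_auto.predict(r_auto[te], g_auto[te]),
            "joint/none": joint_forward(inputs.center_rois[te], jm, train=False)[1],
        }
        for config, sc in preds.items():
            acc = float(((sc >= 0.5).astype(int) == inputs.y[te]).mean())
            rows.append({"permutation": perm, "fold": fold, "config": config,
                         "accuracy": acc})
    per_split = pd.DataFrame(rows)
    piv = per_split.pivot_table(index=["permutation", "fold"], columns="config",
                                values="accuracy")
    configs = ["ref/ref", "ref/auto", "auto/auto", "joint/none"]
    n_comp = len(configs) - 1
    summary_rows = []
    for c in configs:
        rec = {"config": c, "accuracy_mean": piv[c].mean(), "accuracy_sd": piv[c].std(ddof=1)}
        if c != "ref/auto":
            t, p = paired_comparison(piv[c].values, piv["ref/auto"].values, n_comparisons=n_comp)
            rec["t_vs_ref_auto"], rec["p_corrected"] = t, p
        summary_rows.append(rec)
    return per_split, pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# reporting


def render_reports(out_dir, *, stability: dict[str, pd.DataFrame] | None = None,
                   cci: dict[str, pd.DataFrame] | None = None,
                   joint_summary: pd.DataFrame | None = None,
                   raw: dict | None = None) -> list[Path]:
    """Write CSV tables (and a JSON of raw per-split numbers) to out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (stability or {}).items():
        p = out_dir / f"stability_{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    for name, df in (cci or {}).items():
        p = out_dir / f"cci_{name}.csv"
        df.to_csv(p)
        written.append(p)
    if joint_summary is not None:
        p = out_dir / "joint_comparison.csv"
        joint_summary.to_csv(p, index=False)
        written.append(p)
    if raw is not None:
        p = out_dir / "raw_metrics.json"
        p.write_text(json.dumps(raw, indent=2, default=float))
        written.append(p)
    return written


@dataclass
class StudyResults:
    """Headline numbers of one full desk-scale study run."""

    lr_accuracy_by_dice: pd.Series  # pooled over field realizations
    lr_drop: float  # reference minus lowest-Dice accuracy
    lr_spread: float
    masked_accuracy_by_dice: pd.Series
    masked_spread: float
    gated_accuracy_by_dice: pd.Series
    gated_spread: float
    cci_masked: pd.DataFrame
    cci_gated: pd.DataFrame
    cci_masked_mean: float  # mean off-diagonal
    cci_gated_mean: float
    auto_label_dice: float
    joint_summary: pd.DataFrame
    joint_per_split: pd.DataFrame
    targets: list


def _mean_offdiag(M: pd.DataFrame) -> float:
    v = M.values
    n = v.shape[0]
    return float(v[np.triu_indices(n, 1)].mean())


def run_full_study(seed: int = 0, cfg: DeskScaleConfig | None = None,
                   n_field_realizations: int = 3) -> StudyResults:
    """Run all three experiments on one phantom cohort and collect the
    headline quantities.

    The radiomics-LR accuracy curve is averaged over several independent
    perturbation-field realizations (one label family per realization) —
    a single family is one random draw of how each boundary moves, and
    the accuracy-vs-Dice trend is about the expectation over such draws.
    CNN experiments use the first family; each gated classifier trained
    per fold is reused for the reference and automatic-label arms of the
    joint comparison.
    """
    from .radiomics import cohort_feature_matrix

    cfg, cohort, series, inputs = build_desk_study(cfg, seed=seed)
    plan = make_cv_plan(cohort.diagnoses, folds=cfg.folds,
                        n_permutations=cfg.n_permutations, seed=cfg.seed + 2)

    lr_acc = None
    for k in range(n_field_realizations):
        ser = series if k == 0 else make_label_series(
            cohort, cfg.targets, tol=cfg.dice_tol, seed=cfg.seed + 100 + k,
            alpha_max=cfg.alpha_max)
        feats = {lv.target_dice: cohort_feature_matrix(cohort, lv.masks)
                 for lv in ser.levels}
        _, rep = run_population_stability(cohort, ser, "radiomics-lr", plan, cfg,
                                          inputs=inputs, features=feats)
        a = rep.set_index("dice")["accuracy_mean"]
        lr_acc = a if lr_acc is None else lr_acc + a
    lr_acc = lr_acc / n_field_realizations

    masked_table, masked_rep = run_population_stability(
        cohort, series, "pdnet-masked", plan, cfg, inputs=inputs)
    gated_models: dict = {}
    gated_table, gated_rep = run_population_stability(
        cohort, series, "pdnet-gated", plan, cfg, inputs=inputs,
        model_sink=gated_models)

    targets = list(series.targets)
    cci_masked = cci_matrix(masked_table, sources=targets)
    cci_gated = cci_matrix(gated_table, sources=targets)

    sn2_warm, _ = train_sn2(inputs.center_rois, inputs.center_masks, inputs.spacing,
                            cfg.sn2, seed=cfg.seed + 5, epochs=cfg.sn2_epochs,
                            lr=cfg.sn2_lr)
    _, auto_masks, auto_dice = train_auto_segmenter(cohort, inputs, cfg)
    per_split, summary = run_joint_comparison(cohort, inputs, auto_masks, sn2_warm,
                                              plan, cfg, gated_ref_models=gated_models)

    m_acc = masked_rep.set_index("dice")["accuracy_mean"]
    g_acc = gated_rep.set_index("dice")["accuracy_mean"]
    return StudyResults(
        lr_accuracy_by_dice=lr_acc,
        lr_drop=float(lr_acc[1.0] - lr_acc[targets[-1]]),
        lr_spread=float(lr_acc.max() - lr_acc.min()),
        masked_accuracy_by_dice=m_acc,
        masked_spread=float(m_acc.max() - m_acc.min()),
        gated_accuracy_by_dice=g_acc,
        gated_spread=float(g_acc.max() - g_acc.min()),
        cci_masked=cci_masked,
        cci_gated=cci_gated,
        cci_masked_mean=_mean_offdiag(cci_masked),
        cci_gated_mean=_mean_offdiag(cci_gated),
        auto_label_dice=auto_dice,
        joint_summary=summary,
        joint_per_split=per_split,
        targets=targets,
    )


def build_desk_study(cfg: DeskScaleConfig | None = None, seed: int | None = None):
    """Generate the desk-scale cohort, label series and prepared inputs."""
    cfg = cfg or DeskScaleConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cohort = generate_cohort(cfg.n_pd, cfg.n_hc, cfg.phantom, cfg.seed)
    series = make_label_series(cohort, cfg.targets, tol=cfg.dice_tol, seed=cfg.seed + 1,
                               alpha_max=cfg.alpha_max)
    inputs = prepare_inputs(cohort, series, cfg)
    return cfg, cohort, series, inputs
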