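"""PDNet: ROI geometry, masked vs gated conditioning, pooling contracts."""

import numpy as np
import pytest

from nigrastab.grids import BinaryMask, VolumeGrid
from nigrastab.pdnet import (
    ExtractorConfig,
    PDNet,
    TrainConfig,
    center_roi,
    crop_like,
    crop_roi,
    gated_forward,
    gated_pool,
    masked_forward,
    normalize_roi,
    train_classifier,
)

SP = (1.0, 1.0, 1.0)
TINY_CFG = ExtractorConfig(input_roi_shape=(12, 12, 8), conv_specs=((6, 5, 1),),
                           use_norm=False, head_norm=False, head_hidden=4)


def _case(seed=0, shape=(12, 12, 8)):
    rng = np.random.default_rng(seed)
    vol = rng.random(shape)
    mask = np.zeros(shape)
    mask[4:8, 4:8, 3:6] = 1.0
    return vol, mask


class TestCropRoi:
    def test_single_voxel_mask_margin_box(self):
        m = np.zeros((20, 20, 20), dtype=np.uint8)
        m[10, 10, 10] = 1
        vol = VolumeGrid(np.arange(8000, dtype=float).reshape(20, 20, 20), SP)
        roi, roi_m, geom = crop_roi(vol, BinaryMask(m, SP), margin=4, roi_shape=(9, 9, 9))
        assert roi.shape == (9, 9, 9)
        assert roi_m.sum() == 1
        assert roi_m[4, 4, 4] == 1  # voxel centered

    def test_mask_preserved_when_window_fits(self, one_subject):
        vol, mask = one_subject
        roi, roi_m, _ = crop_roi(vol, mask, margin=2, roi_shape=(18, 18, 12))
        assert roi_m.sum() == mask.n_foreground

    def test_identical_geometry_for_volume_and_mask(self, one_subject):
        vol, mask = one_subject
        roi, roi_m, geom = crop_roi(vol, mask, margin=2, roi_shape=(18, 18, 12))
        again = crop_like(vol.values, geom)
        np.testing.assert_array_equal(roi, again)

    def test_empty_mask_rejected(self):
        vol = VolumeGrid(np.zeros((12, 12, 12)), SP)
        with pytest.raises(ValueError):
            crop_roi(vol, BinaryMask(np.zeros((12, 12, 12), dtype=np.uint8), SP))

    def test_center_roi_is_mask_free(self, one_subject):
        vol, _ = one_subject
        roi, geom = center_roi(vol, (18, 18, 12))
        assert roi.shape == (18, 18, 12)


class TestForwardModes:
    def test_all_ones_mask_equals_unmasked(self):
        vol, _ = _case()
        model = PDNet(TINY_CFG, seed=0)
        s_masked = masked_forward(vol, np.ones_like(vol), model)
        s_gated_full = gated_forward(vol, np.ones_like(vol)[None], model)
        # identical input path: masked with full mask == raw forward; and a
        # full-support binary gate reduces gated pooling to plain GAP
        assert s_masked == pytest.approx(float(s_gated_full), abs=1e-12)

    def test_deterministic_inference(self):
        vol, mask = _case(1)
        model = PDNet(TINY_CFG, seed=3)
        assert masked_forward(vol, mask, model) == masked_forward(vol, mask, model)

    def test_masked_scores_respond_to_outside_changes(self):
        # two masks with the same support but different surroundings change
        # the masked input only through the mask itself; changing the image
        # outside the mask support must NOT change the masked score
        vol, mask = _case(2)
        model = PDNet(TINY_CFG, seed=0)
        vol2 = vol.copy()
        vol2[mask == 0] += 1.0
        assert masked_forward(vol, mask, model) == pytest.approx(
            masked_forward(vol2, mask, model))

    def test_gated_activations_identical_across_gates(self):
        """The pooling-level stability contract: with a fixed ROI volume the
        extractor activations are bit-identical for any two gates; only
        the pooled weights differ."""
        vol, mask = _case(3)
        model = PDNet(TINY_CFG, seed=1)
        x = normalize_roi(vol)[None, None]
        fm1 = model.feature_maps(x, train=False)
        fm2 = model.feature_maps(x, train=False)
        np.testing.assert_array_equal(fm1, fm2)
        g1 = mask.copy()
        g2 = np.roll(mask, 1, axis=0)
        s1 = gated_forward(vol, g1[None], model)
        s2 = gated_forward(vol, g2[None], model)
        assert np.isfinite(s1) and np.isfinite(s2)


class TestGatedPool:
    def test_all_ones_gate_reduces_to_gap(self):
        rng = np.random.default_rng(0)
        fm = rng.standard_normal((1, 4, 4, 4, 2))
        ones = np.ones((1, 4, 4, 2))
        for mode in ("weighted-average", "global-mean"):
            np.testing.assert_allclose(gated_pool(fm, ones, mode),
                                       fm.mean(axis=(2, 3, 4)), atol=1e-12)

    def test_binary_gate_equals_in_mask_mean(self):
        rng = np.random.default_rng(1)
        fm = rng.standard_normal((1, 3, 4, 4, 1))
        gate = (rng.random((1, 4, 4, 1)) > 0.5).astype(float)
        pooled = gated_pool(fm, gate, "weighted-average")
        for c in range(3):
            manual = fm[0, c][gate[0] > 0].mean()
            assert pooled[0, c] == pytest.approx(manual)

    def test_invariant_to_perturbations_outside_support(self):
        rng = np.random.default_rng(2)
        fm = rng.standard_normal((1, 2, 4, 4, 2))
        gate = np.zeros((1, 4, 4, 2))
        gate[0, 1:3, 1:3, :] = 1.0
        fm2 = fm.copy()
        fm2[0, :, 0, :, :] += 100.0  # gate-zero voxels only
        for mode in ("weighted-average", "global-mean"):
            np.testing.assert_allclose(gated_pool(fm, gate, mode),
                                       gated_pool(fm2, gate, mode))


@pytest.fixture(scope="module")
def trained(small_params):
    from nigrastab.phantom import generate_cohort

    cohort = generate_cohort(10, 10, small_params, seed=4)
    rois, gates, ys = [], [], []
    for s in cohort:
        v, m, _ = crop_roi(s.volume, s.mask, margin=2, roi_shape=(18, 18, 12))
        rois.append(normalize_roi(v))
        gates.append(m)
        ys.append(1 if s.diagnosis == "PD" else 0)
    rois, gates, ys = np.array(rois), np.array(gates), np.array(ys)
    cfg = ExtractorConfig(input_roi_shape=(18, 18, 12), conv_specs=((6, 5, 1),),
                          use_norm=False, head_norm=True, head_hidden=8)
    clf = train_classifier(rois, gates, ys, mode="masked", cfg=cfg,
                           train_cfg=TrainConfig(epochs=40, lr=1e-2, seed=0))
    return clf, rois, gates, ys


class TestTraining:
    def test_training_accuracy_above_chance(self, trained):
        clf, rois, gates, ys = trained
        acc = (((clf.predict(rois, gates) >= 0.5).astype(int)) == ys).mean()
        assert acc > 0.9

    def test_training_deterministic(self, trained, small_params):
        clf, rois, gates, ys = trained
        cfg = ExtractorConfig(input_roi_shape=(18, 18, 12), conv_specs=((6, 5, 1),),
                              use_norm=False, head_norm=True, head_hidden=8)
        clf2 = train_classifier(rois, gates, ys, mode="masked", cfg=cfg,
                                train_cfg=TrainConfig(epochs=40, lr=1e-2, seed=0))
        np.testing.assert_allclose(clf.predict(rois, gates), clf2.predict(rois, gates))

    def test_single_class_split_rejected(self, trained):
        _, rois, gates, ys = trained
        with pytest.raises(ValueError):
            train_classifier(rois[:4], gates[:4], np.ones(4), mode="masked",
                             cfg=ExtractorConfig(input_roi_shape=(18, 18, 12),
                                                 conv_specs=((6, 5, 1),)))

    def test_null_cohort_auc_near_chance(self):
        """Zero-contrast cohort: held-out AUC stays near 0.5."""
        from nigrastab.metrics import auc_rank
        from nigrastab.phantom import PhantomParams, generate_cohort

        params = PhantomParams(grid_shape=(24, 24, 16), spacing=(1, 1, 1),
                               nucleus_radius_range=(2.4, 2.9),
                               bilateral_offset_frac=0.15,
                               pd_mean=90.000001, hc_mean=90.0, pd_sd=15.0, hc_sd=15.0)
        cohort = generate_cohort(12, 12, params, seed=9)
        rois, gates, ys = [], [], []
        for s in cohort:
            v, m, _ = crop_roi(s.volume, s.mask, margin=2, roi_shape=(18, 18, 12))
            rois.append(normalize_roi(v)); gates.append(m)
            ys.append(1 if s.diagnosis == "PD" else 0)
        rois, gates, ys = np.array(rois), np.array(gates), np.array(ys)
        order = np.random.default_rng(0).permutation(len(ys))  # mix classes
        rois, gates, ys = rois[order], gates[order], ys[order]
        cfg = ExtractorConfig(input_roi_shape=(18, 18, 12), conv_specs=((6, 5, 1),),
                              use_norm=False, head_norm=True, head_hidden=8)
        clf = train_classifier(rois[:16], gates[:16], ys[:16], mode="masked", cfg=cfg,
                               train_cfg=TrainConfig(epochs=10, lr=1e-2, seed=0))
        scores = clf.predict(rois[16:], gates[16:])
        auc = auc_rank(scores[ys[16:] == 1], scores[ys[16:] == 0])
        assert abs(auc - 0.5) <= 0.35  # tiny held-out set: wide tolerance
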