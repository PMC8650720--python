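"""Radiomics arm: extraction oracles, ICC screen, RFE logistic model."""

import numpy as np
import pandas as pd
import pytest

from nigrastab.grids import BinaryMask, VolumeGrid
from nigrastab.labels import make_label_series
from nigrastab.radiomics import (
    LinearClassifier,
    cohort_feature_matrix,
    extract_features,
    glcm_counts,
    icc_screen,
    predict_scores,
    rfe_train,
)

SP = (1.0, 1.0, 1.0)


def _vol(arr):
    return VolumeGrid(np.asarray(arr, dtype=float), SP)


def _msk(arr):
    return BinaryMask(np.asarray(arr, dtype=np.uint8), SP)


def _embed(values2d):
    """Place a small 2D patch into a 10x10x10 volume with matching mask."""
    vol = np.zeros((10, 10, 10))
    msk = np.zeros((10, 10, 10), dtype=np.uint8)
    patch = np.asarray(values2d, dtype=float)
    vol[2 : 2 + patch.shape[0], 2 : 2 + patch.shape[1], 5] = patch
    msk[2 : 2 + patch.shape[0], 2 : 2 + patch.shape[1], 5] = 1
    return _vol(vol), _msk(msk)


class TestExtractFeatures:
    def test_constant_region_degenerate_values(self):
        vol, msk = _embed(np.full((3, 3), 7.0))
        f = extract_features(vol, msk)
        assert f["fo_mean"] == 7.0
        assert f["fo_sd"] == 0.0
        assert f["fo_entropy"] == 0.0
        assert f["glcm_energy"] == 1.0  # single gray level

    def test_hand_built_first_order(self):
        vol, msk = _embed([[1.0, 2.0], [3.0, 4.0]])
        f = extract_features(vol, msk)
        assert f["fo_mean"] == pytest.approx(2.5)
        assert f["fo_median"] == pytest.approx(2.5)
        assert f["fo_min"] == 1.0 and f["fo_max"] == 4.0
        assert f["fo_p10"] == pytest.approx(np.percentile([1, 2, 3, 4], 10))
        assert f["fo_p90"] == pytest.approx(np.percentile([1, 2, 3, 4], 90))
        assert f["fo_energy"] == pytest.approx(1 + 4 + 9 + 16)
        assert f["sh_voxel_count"] == 4

    def test_glcm_counts_against_manual_tally(self):
        # 1D strip [0, 1, 0, 1] binned to levels {0, 15}: offset (1,0,0)
        # pairs are (0,1),(1,0),(0,1) -> symmetric counts
        binned = np.zeros((4, 1, 1), dtype=int)
        binned[[1, 3], 0, 0] = 15
        mask = np.ones((4, 1, 1), dtype=bool)
        counts = glcm_counts(binned, mask, (1, 0, 0))
        assert counts[0, 15] == 3 and counts[15, 0] == 3
        assert counts.sum() == 6

    def test_checkerboard_glcm_contrast_brute_force(self):
        patch = np.indices((4, 4)).sum(axis=0) % 2 * 10.0 + 1.0
        vol, msk = _embed(patch)
        f = extract_features(vol, msk)
        # brute force over the 13 directions on the embedded patch
        from nigrastab.radiomics import _DIRECTIONS, N_GLCM_LEVELS

        vals = vol.values
        m = msk.as_bool()
        lo, hi = vals[m].min(), vals[m].max()
        b = np.clip(np.floor((vals - lo) / (hi - lo) * N_GLCM_LEVELS), 0,
                    N_GLCM_LEVELS - 1).astype(int)
        total = np.zeros((N_GLCM_LEVELS, N_GLCM_LEVELS))
        for d in _DIRECTIONS:
            total += glcm_counts(b, m, d)
        p = total / total.sum()
        i, j = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        assert f["glcm_contrast"] == pytest.approx(((i - j) ** 2 * p).sum())

    def test_determinism(self, one_subject):
        vol, msk = one_subject
        f1, f2 = extract_features(vol, msk), extract_features(vol, msk)
        pd.testing.assert_series_equal(f1, f2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_features(_vol(np.zeros((8, 8, 8))), _msk(np.zeros((8, 8, 8))))


class TestIccScreen:
    def _frame(self, cols):
        return pd.DataFrame(cols, index=[f"s{i}" for i in range(len(next(iter(cols.values()))))])

    def test_identical_nonconstant_feature_kept(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(12)
        ref = self._frame({"f": base})
        other = self._frame({"f": base.copy()})
        assert icc_screen(ref, other).kept_names == ["f"]

    def test_noise_replaced_feature_dropped(self):
        rng = np.random.default_rng(1)
        ref = self._frame({"f": rng.standard_normal(30)})
        other = self._frame({"f": rng.standard_normal(30)})
        assert icc_screen(ref, other).kept_names == []

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(20)
        ref = self._frame({"f": base})
        other = self._frame({"f": base})
        res = icc_screen(ref, other, threshold=1.0)  # ICC == 1.0 exactly
        assert res.kept_names == []  # strict inequality: equality fails

    def test_feature_must_pass_every_pairing(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(25)
        ref = self._frame({"f": base})
        good = self._frame({"f": base + 1e-6 * rng.standard_normal(25)})
        bad = self._frame({"f": rng.standard_normal(25)})
        assert icc_screen(ref, [good]).kept_names == ["f"]
        assert icc_screen(ref, [good, bad]).kept_names == []


def _xy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["PD"] * (n // 2) + ["HC"] * (n // 2))
    signal = np.where(y == "PD", 1.0, -1.0) + 0.3 * rng.standard_normal(n)
    X = pd.DataFrame({"signal": signal})
    for i in range(10):
        X[f"noise{i}"] = rng.standard_normal(n)
    return X, y


class TestRfe:
    def test_informative_feature_survives(self):
        X, y = _xy()
        model = rfe_train(X, y, n_final=1)
        assert model.feature_names == ["signal"]

    def test_n_final_equals_feature_count_keeps_all(self):
        X, y = _xy()
        model = rfe_train(X, y, n_final=X.shape[1])
        assert set(model.feature_names) == set(X.columns)

    def test_duplicate_informative_feature_tiebreak(self):
        X, y = _xy()
        X["signal_copy"] = X["signal"].values
        model = rfe_train(X, y, n_final=1)
        assert model.feature_names[0] in ("signal", "signal_copy")

    def test_always_returns_exactly_k(self):
        X, y = _xy()
        for k in (1, 3, 5):
            assert len(rfe_train(X, y, n_final=k).feature_names) == k

    def test_column_order_invariance(self):
        X, y = _xy()
        m1 = rfe_train(X, y, n_final=3)
        m2 = rfe_train(X[list(X.columns)[::-1]], y, n_final=3)
        assert sorted(m1.feature_names) == sorted(m2.feature_names)
        s1 = predict_scores(m1, X)
        s2 = predict_scores(m2, X[list(X.columns)[::-1]])
        np.testing.assert_allclose(s1, s2, atol=1e-8)


class TestPredictScores:
    def test_zero_model_gives_half(self):
        model = LinearClassifier(["a"], np.zeros(1), 0.0, np.zeros(1), np.ones(1))
        X = pd.DataFrame({"a": [1.0, -5.0, 100.0]})
        np.testing.assert_allclose(predict_scores(model, X), 0.5)

    def test_closed_form_two_features(self):
        model = LinearClassifier(["a", "b"], np.array([1.0, -2.0]), 0.5,
                                 np.array([0.0, 1.0]), np.array([2.0, 1.0]))
        X = pd.DataFrame({"a": [2.0], "b": [3.0]})
        lin = 1.0 * (2.0 / 2.0) - 2.0 * (3.0 - 1.0) + 0.5
        assert predict_scores(model, X)[0] == pytest.approx(1 / (1 + np.exp(-lin)))

    def test_large_intercept_saturates(self):
        model = LinearClassifier(["a"], np.zeros(1), 50.0, np.zeros(1), np.ones(1))
        assert predict_scores(model, pd.DataFrame({"a": [0.0]}))[0] == pytest.approx(1.0)

    def test_missing_column_named_in_error(self):
        model = LinearClassifier(["a", "b"], np.ones(2), 0.0, np.zeros(2), np.ones(2))
        with pytest.raises(ValueError, match="b"):
            predict_scores(model, pd.DataFrame({"a": [1.0]}))


class TestLabelSensitivity:
    def test_first_order_drift_grows_as_dice_falls(self, tiny_cohort):
        """The mechanism behind the population-level accuracy decline:
        first-order features drift monotonically away from their
        reference values as the labels deviate."""
        series = make_label_series(tiny_cohort, targets=(0.95, 0.90, 0.85),
                                   tol=0.01, seed=3, alpha_max=25.0)
        mats = {lv.target_dice: cohort_feature_matrix(tiny_cohort, lv.masks)
                for lv in series.levels}
        fo_cols = [c for c in mats[1.0].columns if c.startswith("fo_")]
        drifts = []
        for t in (0.95, 0.90, 0.85):
            rel = ((mats[t][fo_cols] - mats[1.0][fo_cols]).abs()
                   / mats[1.0][fo_cols].abs().clip(lower=1e-9)).mean().mean()
            drifts.append(rel)
        assert drifts[0] > 0
        assert drifts[0] < drifts[1] < drifts[2]
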