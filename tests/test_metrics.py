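"""Metric oracles: Dice, signed distance, ICC(2,1), CCI, panel, paired tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nigrastab.grids import BinaryMask
from nigrastab.metrics import (
    ICC_DEGENERATE,
    PredictionTable,
    auc_rank,
    cci,
    cci_matrix,
    classification_panel,
    dice_coefficient,
    icc_2_1,
    paired_comparison,
    signed_distance,
)


def _mask(arr):
    a = np.asarray(arr, dtype=np.uint8)
    return BinaryMask(a, (1.0, 1.0, 1.0))


class TestDice:
    def test_hand_counted_cases(self):
        a = np.zeros((3, 3, 1), dtype=np.uint8)
        b = np.zeros((3, 3, 1), dtype=np.uint8)
        a[0:2, 0:2, 0] = 1  # |A| = 4
        b[1:3, 0:2, 0] = 1  # |B| = 4, overlap = 2
        assert dice_coefficient(_mask(a), _mask(b)) == pytest.approx(2 * 2 / 8)
        assert dice_coefficient(_mask(a), _mask(a)) == 1.0
        c = np.zeros_like(a)
        c[2, 2, 0] = 1
        assert dice_coefficient(_mask(a), _mask(c)) == 0.0

    def test_empty_vs_empty_is_one(self):
        z = np.zeros((3, 3, 3))
        assert dice_coefficient(z, z) == 1.0

    @given(st.integers(0, 2**27 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((4, 4, 4)) > 0.5
        b = rng.random((4, 4, 4)) > 0.5
        d1, d2 = dice_coefficient(a, b), dice_coefficient(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0
        # simultaneous translation leaves Dice unchanged
        assert dice_coefficient(np.roll(a, 1, 0), np.roll(b, 1, 0)) == pytest.approx(d1)


class TestSignedDistance:
    def test_single_voxel_geometry(self):
        m = np.zeros((9, 9, 9), dtype=np.uint8)
        m[4, 4, 4] = 1
        sd = signed_distance(_mask(m)).values
        assert sd[4, 4, 4] < 0
        assert sd[5, 4, 4] == pytest.approx(1.0)
        assert sd[4, 4, 6] == pytest.approx(2.0)

    def test_sign_convention_matches_mask(self, box_mask):
        sd = signed_distance(box_mask).values
        np.testing.assert_array_equal(sd < 0, box_mask.as_bool())

    def test_magnitude_vs_brute_force(self, box_mask):
        sd = signed_distance(box_mask).values
        fg = np.argwhere(box_mask.as_bool())
        bg = np.argwhere(~box_mask.as_bool())
        rng = np.random.default_rng(0)
        for idx in rng.choice(len(bg), size=10, replace=False):
            p = bg[idx]
            brute = np.sqrt(((fg - p) ** 2).sum(axis=1)).min()
            assert sd[tuple(p)] == pytest.approx(brute)
        for idx in rng.choice(len(fg), size=5, replace=False):
            p = fg[idx]
            brute = np.sqrt(((bg - p) ** 2).sum(axis=1)).min()
            assert -sd[tuple(p)] == pytest.approx(brute)

    def test_anisotropic_spacing(self):
        m = np.zeros((9, 9, 9), dtype=np.uint8)
        m[4, 4, 4] = 1
        sd = signed_distance(BinaryMask(m, (1.0, 1.0, 2.0))).values
        assert sd[4, 4, 5] == pytest.approx(2.0)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            signed_distance(_mask(np.ones((4, 4, 4))))


def _anova_icc_oracle(x):
    """Independent two-way ANOVA decomposition (textbook sums of squares)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(0) - grand) ** 2) / (k - 1)
    sse = np.sum((x - x.mean(1, keepdims=True) - x.mean(0) + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_2_1(x) == pytest.approx(1.0)

    def test_offset_penalized_on_hand_built_matrix(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x = np.column_stack([col, col + 20.0])
        val = icc_2_1(x)
        assert val == pytest.approx(_anova_icc_oracle(x), abs=1e-12)
        assert val < 0.2  # absolute agreement punishes the offset

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((50, 2))
        assert abs(icc_2_1(x)) < 0.3

    def test_matches_anova_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal((20, 2)) + rng.standard_normal((20, 1))
            assert icc_2_1(x) == pytest.approx(_anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.standard_normal((15, 2)) + 2 * rng.standard_normal((15, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile(["a", "b"], 15),
            "score": x.ravel(),
        })
        res = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        # two-way random effects, absolute agreement, single rater
        expected = res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_2_1(x) == pytest.approx(expected, abs=1e-6)

    def test_constant_matrix_degenerate_sentinel(self):
        x = np.full((5, 2), 3.0)
        assert icc_2_1(x) == ICC_DEGENERATE
        assert not icc_2_1(x) > 0.8  # fails any screen


def _ptable(preds, subjects=None):
    subjects = subjects or [f"s{i}" for i in range(len(preds))]
    return pd.DataFrame({
        "subject_id": subjects,
        "label_source": 1.0,
        "true_class": "PD",
        "predicted_class": preds,
        "score": [0.9 if p == "PD" else 0.1 for p in preds],
    })


class TestCCI:
    def test_worked_fraction(self):
        n, agree = 1000, 926
        a = _ptable(["PD"] * n)
        b_preds = ["PD"] * agree + ["HC"] * (n - agree)
        b = _ptable(b_preds)
        assert cci(a, b) == pytest.approx(0.926)

    def test_identity_and_total_disagreement(self):
        a = _ptable(["PD", "HC", "PD", "HC", "PD", "PD", "HC", "PD", "HC", "PD"])
        assert cci(a, a) == 1.0
        flipped = a.copy()
        flipped["predicted_class"] = np.where(a["predicted_class"] == "PD", "HC", "PD")
        assert cci(a, flipped) == 0.0

    def test_subject_mismatch_raises(self):
        a = _ptable(["PD"] * 3, ["s0", "s1", "s2"])
        b = _ptable(["PD"] * 3, ["s0", "s1", "s9"])
        with pytest.raises(ValueError, match="differ"):
            cci(a, b)

    @given(st.integers(0, 2**27 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matrix_symmetric_unit_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for src in (1.0, 0.9, 0.8):
            for i in range(8):
                p = rng.choice(["PD", "HC"])
                rows.append({"subject_id": f"s{i}", "label_source": src,
                             "true_class": "PD" if i < 4 else "HC",
                             "predicted_class": p, "score": 0.9 if p == "PD" else 0.1})
        table = PredictionTable(pd.DataFrame(rows))
        M = cci_matrix(table)
        np.testing.assert_allclose(M.values, M.values.T)
        np.testing.assert_allclose(np.diag(M.values), 1.0)
        assert ((M.values >= 0) & (M.values <= 1)).all()


def _slice(scores_pd, scores_hc, threshold=0.5):
    scores = list(scores_pd) + list(scores_hc)
    truth = ["PD"] * len(scores_pd) + ["HC"] * len(scores_hc)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(scores))],
        "label_source": 1.0,
        "true_class": truth,
        "predicted_class": ["PD" if s >= threshold else "HC" for s in scores],
        "score": scores,
    })


class TestClassificationPanel:
    def test_hand_computed_auc(self):
        # pairs: (.9,.5)+ (.9,.3)+ (.6,.5)+ (.6,.3)+ (.4,.5)- (.4,.3)+ -> 5/6
        panel = classification_panel(_slice([0.9, 0.6, 0.4], [0.5, 0.3]))
        assert panel.auc == pytest.approx(5 / 6)
        # and with an exact tie, half credit
        assert auc_rank([0.5, 0.9], [0.5]) == pytest.approx((0.5 + 1.0) / 2)

    def test_perfect_and_anti_ordered(self):
        perfect = classification_panel(_slice([0.8, 0.9], [0.1, 0.2]))
        assert perfect.auc == 1.0 and perfect.accuracy == 1.0
        anti = classification_panel(_slice([0.1, 0.2], [0.8, 0.9]))
        assert anti.auc == 0.0

    def test_bac_is_mean_of_recalls(self):
        p = classification_panel(_slice([0.9, 0.2, 0.7], [0.1, 0.8]))
        assert p.bac == pytest.approx((p.sensitivity + p.specificity) / 2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_panel(_slice([0.9, 0.8], []))

    @given(st.integers(0, 2**27 - 1))
    @settings(max_examples=25, deadline=None)
    def test_auc_rank_equals_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 6, size=rng.integers(1, 20)) / 5.0
        neg = rng.integers(0, 6, size=rng.integers(1, 20)) / 5.0
        brute = np.mean([
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        ])
        assert auc_rank(pos, neg) == pytest.approx(brute)
        # cross-check against sklearn on tie-free samples
        if len(np.unique(np.concatenate([pos, neg]))) == len(pos) + len(neg):
            from sklearn.metrics import roc_auc_score

            y = [1] * len(pos) + [0] * len(neg)
            assert auc_rank(pos, neg) == pytest.approx(
                roc_auc_score(y, np.concatenate([pos, neg])))


class TestPairedComparison:
    def test_identical_inputs_give_p_one(self):
        a = [0.8, 0.85, 0.9, 0.8]
        t, p = paired_comparison(a, a)
        assert (t, p) == (0.0, 1.0)

    def test_constant_difference_with_jitter_significant(self):
        rng = np.random.default_rng(0)
        b = 0.8 + rng.normal(0, 1e-3, size=10)
        a = b + 0.05 + rng.normal(0, 1e-3, size=10)
        t, p = paired_comparison(a, b, n_comparisons=3)
        assert p < 0.05
        # closed-form check of the t statistic
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(expected_t)

    def test_correction_never_lowers_p(self):
        rng = np.random.default_rng(3)
        a = rng.random(8)
        b = rng.random(8)
        _, p1 = paired_comparison(a, b, n_comparisons=1)
        _, p4 = paired_comparison(a, b, n_comparisons=4)
        assert p4 >= p1
        assert p4 <= 1.0
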