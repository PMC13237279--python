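"""Metrics against brute-force oracles; significance tests; fold aggregation."""

import numpy as np
import pytest
from scipy import stats

from kitefusion.metrics_stats import (
    AggregateReport,
    BinaryMaskPair,
    FoldResults,
    accuracy,
    auc,
    average_hausdorff,
    dice_coefficient,
    fold_aggregate,
    iou,
    load_published_folds,
    paired_t_test,
    sensitivity_specificity,
    welch_t_test,
)


def random_mask_pair(rng, shape=(8, 8), p=0.3):
    return BinaryMaskPair(
        (rng.random(shape) < p).astype(np.uint8),
        (rng.random(shape) < p).astype(np.uint8),
    )


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        m = (rng.random((6, 6)) < 0.4).astype(np.uint8)
        m[0, 0] = 1
        pair = BinaryMaskPair(m, m)
        assert dice_coefficient(pair) == 1.0
        assert iou(pair) == 1.0

    def test_small_worked_example(self):
        pred = np.zeros((1, 4), np.uint8)
        pred[0, :2] = 1  # {(0,0),(0,1)}
        ref = np.zeros((1, 4), np.uint8)
        ref[0, 1:3] = 1  # {(0,1),(0,2)}
        pair = BinaryMaskPair(pred, ref)
        assert dice_coefficient(pair) == pytest.approx(0.5)
        assert iou(pair) == pytest.approx(1 / 3)

    def test_disjoint_and_both_empty(self):
        a = np.zeros((3, 3), np.uint8)
        b = np.zeros((3, 3), np.uint8)
        assert dice_coefficient(BinaryMaskPair(a, b)) == 1.0
        assert iou(BinaryMaskPair(a, b)) == 1.0
        a2 = a.copy()
        a2[0, 0] = 1
        b2 = b.copy()
        b2[2, 2] = 1
        assert iou(BinaryMaskPair(a2, b2)) == 0.0

    def test_brute_force_pixel_counting(self, rng):
        for _ in range(200):
            pair = random_mask_pair(rng)
            inter = sum(
                int(pair.predicted[i, j]) and int(pair.reference[i, j])
                for i in range(8)
                for j in range(8)
            )
            np_, nr = pair.predicted.sum(), pair.reference.sum()
            if np_ + nr:
                assert dice_coefficient(pair) == 2 * inter / (np_ + nr)

    def test_dice_iou_duality(self, rng):
        for _ in range(200):
            pair = random_mask_pair(rng)
            d = dice_coefficient(pair)
            assert iou(pair) == pytest.approx(d / (2 - d), abs=1e-12)

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(ValueError):
            BinaryMaskPair(np.full((2, 2), 3), np.zeros((2, 2)))


class TestAverageHausdorff:
    def test_identical_masks_give_zero(self, rng):
        m = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        m[5, 5] = 1
        assert average_hausdorff(BinaryMaskPair(m, m)) == 0.0

    def test_two_single_pixels_three_apart(self):
        a = np.zeros((5, 8), np.uint8)
        b = np.zeros((5, 8), np.uint8)
        a[2, 1] = 1
        b[2, 4] = 1
        assert average_hausdorff(BinaryMaskPair(a, b)) == pytest.approx(3.0)

    def test_matches_exhaustive_nearest_neighbour(self, rng):
        for _ in range(50):
            pair = random_mask_pair(rng, (14, 14), p=0.25)
            if not (pair.predicted.any() and pair.reference.any()):
                continue
            a = np.argwhere(pair.predicted).astype(float)
            b = np.argwhere(pair.reference).astype(float)
            d_ab = np.mean(
                [min(np.hypot(*(p - q)) for q in b) for p in a]
            )
            d_ba = np.mean(
                [min(np.hypot(*(p - q)) for q in a) for p in b]
            )
            assert average_hausdorff(pair) == pytest.approx(
                (d_ab + d_ba) / 2, abs=1e-9
            )

    def test_symmetry(self, rng):
        p = random_mask_pair(rng, (12, 12))
        p.predicted[0, 0] = 1
        p.reference[5, 5] = 1
        fwd = average_hausdorff(p)
        rev = average_hausdorff(BinaryMaskPair(p.reference, p.predicted))
        assert fwd == pytest.approx(rev, abs=1e-12)

    def test_empty_prediction_penalized_with_diagonal(self):
        ref = np.zeros((9, 9), np.uint8)
        ref[4, 4] = 1
        with pytest.warns(UserWarning):
            d = average_hausdorff(BinaryMaskPair(np.zeros((9, 9), np.uint8), ref))
        assert d == pytest.approx(np.hypot(8, 8))

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            average_hausdorff(
                BinaryMaskPair(np.ones((3, 3), np.uint8), np.zeros((3, 3), np.uint8))
            )


class TestClassificationMetrics:
    def test_all_correct(self):
        y = ["benign", "malignant", "malignant"]
        assert accuracy(y, y) == 1.0

    def test_confusion_counts_example(self):
        true = ["malignant"] * 2 + ["benign"] * 4
        pred = ["malignant"] * 2 + ["malignant"] + ["benign"] * 3
        # TP=2 FP=1 TN=3 FN=0
        sens, spec = sensitivity_specificity(pred, true)
        assert sens == 1.0 and spec == pytest.approx(0.75)
        assert accuracy(pred, true) == pytest.approx(5 / 6)

    def test_accuracy_invariant_to_order(self, rng):
        true = np.array(["benign", "malignant"] * 5)
        pred = np.array(["malignant", "benign"] * 5)
        perm = rng.permutation(10)
        assert accuracy(pred, true) == accuracy(pred[perm], true[perm])

    def test_auc_perfect_separation(self):
        scores = [0.9, 0.8, 0.3, 0.2]
        labels = ["malignant", "malignant", "benign", "benign"]
        assert auc(scores, labels) == 1.0

    def test_auc_all_ties_is_half(self):
        assert auc([0.5] * 6, ["malignant"] * 3 + ["benign"] * 3) == 0.5

    def test_auc_pair_enumeration_example(self):
        scores = [0.9, 0.4, 0.6, 0.2]
        labels = ["malignant", "malignant", "benign", "benign"]
        # concordant pairs: (0.9>0.6), (0.9>0.2), (0.4<0.6 no), (0.4>0.2) => 3/4
        assert auc(scores, labels) == pytest.approx(0.75)

    def test_auc_matches_mann_whitney_enumeration(self, rng):
        for _ in range(20):
            n_pos, n_neg = rng.integers(2, 6), rng.integers(2, 6)
            scores = np.round(rng.random(n_pos + n_neg), 1)
            labels = ["malignant"] * n_pos + ["benign"] * n_neg
            pos, neg = scores[:n_pos], scores[n_pos:]
            u = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert auc(scores, labels) == pytest.approx(u / (n_pos * n_neg))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], ["benign", "benign"])


class TestSignificanceTests:
    def test_identical_sequences_give_p_one(self):
        assert paired_t_test([1, 2, 3], [1, 2, 3]) == 1.0
        assert welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_paired_symmetry(self):
        a = [0.8, 0.82, 0.79, 0.85, 0.81]
        b = [0.75, 0.77, 0.80, 0.78, 0.74]
        assert paired_t_test(a, b) == pytest.approx(paired_t_test(b, a))

    def test_paired_closed_form_example(self):
        d = np.array([0.04, 0.038, 0.05, 0.039, 0.022])
        # independent route: closed-form t statistic + t CDF
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_expected = 2 * stats.t.sf(abs(t_stat), df=len(d) - 1)
        assert t_stat == pytest.approx(8.47, abs=0.1)
        p = paired_t_test(d, np.zeros_like(d))
        assert p == pytest.approx(p_expected, rel=1e-10)
        assert p == pytest.approx(0.0011, abs=2e-4)

    def test_welch_scale_invariance(self):
        a = [1.0, 1.2, 0.9, 1.4]
        b = [2.0, 2.5, 1.8, 2.2]
        assert welch_t_test(a, b) == pytest.approx(
            welch_t_test([10 * x for x in a], [10 * x for x in b])
        )

    def test_welch_agrees_with_permutation_test(self):
        rng = np.random.default_rng(0)
        a = np.array([0.828, 0.84, 0.815, 0.83, 0.822])
        b = np.array([0.823, 0.81, 0.835, 0.82, 0.828])
        obs = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:5].mean() - perm[5:].mean()) >= obs - 1e-15:
                count += 1
        p_perm = count / n_perm
        assert abs(welch_t_test(a, b) - p_perm) < 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestFoldAggregation:
    def test_published_final_model_row(self):
        folds = load_published_folds()["loss_ablation"]["model_carvemix_dicece"]
        agg = fold_aggregate(FoldResults("final", dict(folds)))
        assert agg.rounded_mean("dice") == pytest.approx(0.826)
        assert agg.rounded_mean("iou") == pytest.approx(0.703)
        assert round(agg.mean["ahd_px"], 1) == pytest.approx(4.3)

    def test_published_kitenet_row(self):
        folds = load_published_folds()["branch_ablation"]["KiteNet"]
        agg = fold_aggregate(FoldResults("kite", dict(folds)))
        assert agg.rounded_mean("dice") == pytest.approx(0.444)

    def test_constant_folds_have_zero_sd(self):
        agg = fold_aggregate(FoldResults("m", {"dice": [0.8] * 5}))
        assert agg.sd["dice"] == 0.0
        assert agg.mean["dice"] == pytest.approx(0.8)

    def test_mean_and_sample_sd_definition(self, rng):
        vals = rng.random(5).tolist()
        agg = fold_aggregate(FoldResults("m", {"x": vals}))
        assert agg.mean["x"] == pytest.approx(np.mean(vals))
        assert agg.sd["x"] == pytest.approx(np.std(vals, ddof=1))

    def test_requires_two_folds(self):
        with pytest.raises(ValueError):
            fold_aggregate(FoldResults("m", {"dice": [0.8]}))

    def test_ragged_metrics_rejected(self):
        with pytest.raises(ValueError):
            FoldResults("m", {"a": [1, 2], "b": [1, 2, 3]})

    def test_report_type(self):
        agg = fold_aggregate(FoldResults("m", {"dice": [0.1, 0.2, 0.3]}))
        assert isinstance(agg, AggregateReport)
        assert agg.model == "m"
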