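"""Evaluation metrics against exhaustive brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungseg.metrics import (ConfusionCounts, MetricsReport, aggregate_report,
                             basic_stats, confusion, dice, gce, iou, pri,
                             roc_auc, voi)

from conftest import all_partitions


# ---------------------------------------------------------------- oracles

def brute_rand(a, b) -> float:
    n = len(a)
    agree = sum(
        (a[i] == a[j]) == (b[i] == b[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return agree / math.comb(n, 2)


def brute_voi(a, b) -> float:
    n = len(a)

    def H(labels):
        return -sum(
            (c / n) * math.log2(c / n)
            for c in (labels.count(v) for v in set(labels))
        )

    joint = [(x, y) for x, y in zip(a, b)]
    h_joint = H(joint)
    return 2 * h_joint - H(list(a)) - H(list(b))  # H(a|b)+H(b|a)


def brute_gce(a, b) -> float:
    n = len(a)

    def refinement_error(s, t):
        total = 0.0
        for x in range(n):
            rs = {i for i in range(n) if s[i] == s[x]}
            rt = {i for i in range(n) if t[i] == t[x]}
            total += len(rs - rt) / len(rs)
        return total / n

    return min(refinement_error(a, b), refinement_error(b, a))


def brute_auc(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------- tests

class TestPartitionMetricsExhaustive:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_all_partition_pairs_match_brute_force(self, n):
        parts = all_partitions(n)
        for a in parts:
            for b in parts:
                sa, sb = np.array(a), np.array(b)
                assert pri(sa, sb) == pytest.approx(brute_rand(a, b), abs=1e-12)
                assert voi(sa, sb) == pytest.approx(brute_voi(a, b), abs=1e-12)
                assert gce(sa, sb) == pytest.approx(brute_gce(a, b), abs=1e-12)

    def test_size_six_sampled_pairs_match_brute_force(self, rng):
        parts = all_partitions(6)
        idx = rng.integers(0, len(parts), size=(300, 2))
        for i, j in idx:
            a, b = parts[i], parts[j]
            sa, sb = np.array(a), np.array(b)
            assert pri(sa, sb) == pytest.approx(brute_rand(a, b), abs=1e-12)
            assert voi(sa, sb) == pytest.approx(brute_voi(a, b), abs=1e-12)
            assert gce(sa, sb) == pytest.approx(brute_gce(a, b), abs=1e-12)

    def test_worked_example_four_pixels(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        assert pri(a, b) == pytest.approx(1 / 3)
        assert voi(a, b) == pytest.approx(2.0)

    def test_refinement_gives_zero_gce(self):
        coarse = np.array([0, 0, 0, 1, 1, 1])
        fine = np.array([0, 0, 1, 2, 2, 3])  # strict refinement of coarse
        assert gce(fine, coarse) == pytest.approx(0.0, abs=1e-12)

    def test_identical_partitions(self):
        a = np.array([0, 1, 1, 2, 0])
        assert pri(a, a) == 1.0
        assert voi(a, a) == pytest.approx(0.0, abs=1e-12)
        assert gce(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 4, 30)
        perm = np.array([2, 0, 1])
        assert pri(perm[a], b) == pytest.approx(pri(a, b))
        assert voi(perm[a], b) == pytest.approx(voi(a, b))
        assert gce(perm[a], b) == pytest.approx(gce(a, b))

    def test_voi_symmetry(self, rng):
        a, b = rng.integers(0, 3, 40), rng.integers(0, 5, 40)
        assert voi(a, b) == pytest.approx(voi(b, a))

    def test_pri_matches_sklearn_rand_score(self, rng):
        from sklearn.metrics import rand_score

        a, b = rng.integers(0, 4, 60), rng.integers(0, 3, 60)
        assert pri(a, b) == pytest.approx(rand_score(a, b), abs=1e-12)


class TestOverlapMetrics:
    def test_dice_worked_example(self):
        # A={(0,0),(0,1)}, B={(0,1),(1,1)}: |A^B|=1, sizes 2+2
        a = np.array([[1, 1], [0, 0]], bool)
        b = np.array([[0, 1], [0, 1]], bool)
        assert dice(a, b) == pytest.approx(0.5)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        a = np.array([1, 1, 0, 0], bool)
        assert dice(a, a) == 1.0 and iou(a, a) == 1.0
        b = ~a
        assert dice(a, b) == 0.0 and iou(a, b) == 0.0

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z) == 1.0 and iou(z, z) == 1.0

    @given(st.integers(0, 2**30 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_f1_equals_dice_and_iou_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) > 0.5
        b = rng.random((6, 6)) > 0.5
        d = dice(a, b)
        assert iou(a, b) == pytest.approx(d / (2 - d), abs=1e-12)
        f1 = basic_stats(confusion(a, b))["f1"]
        if np.isnan(f1):
            assert d == 1.0  # both empty
        else:
            assert f1 == pytest.approx(d, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestConfusionStats:
    def test_counts_sum_and_worked_example(self):
        pred = np.array([1] * 10 + [0] * 10, bool)
        truth = np.array([1] * 9 + [0, 1] + [0] * 9, bool)
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (9, 1, 1, 9)
        assert c.total == 20
        s = basic_stats(c)
        assert s["sensitivity"] == pytest.approx(0.9)
        assert s["specificity"] == pytest.approx(0.9)
        assert s["accuracy"] == pytest.approx(0.9)

    def test_perfect_prediction(self):
        t = np.array([1, 0, 1, 0], bool)
        s = basic_stats(confusion(t, t))
        assert all(v == 1.0 for v in s.values())

    def test_complement_prediction(self):
        t = np.array([1, 0, 1, 0], bool)
        c = confusion(~t, t)
        assert c.tp == 0 and c.tn == 0

    def test_zero_denominator_yields_nan_not_exception(self):
        s = basic_stats(ConfusionCounts(0, 0, 0, 4))
        assert math.isnan(s["sensitivity"]) and math.isnan(s["precision"])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert auc == 1.0

    def test_all_equal_scores(self):
        auc, _ = roc_auc(np.full(10, 0.5), np.array([0, 1] * 5))
        assert auc == pytest.approx(0.5)

    def test_worked_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        auc, (fpr, tpr) = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    @given(st.integers(0, 2**30 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(20), 2)  # coarse grid to exercise ties
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            return
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)

    def test_single_class_truth_is_undefined(self):
        auc, curve = roc_auc(np.array([0.2, 0.7]), np.array([1, 1]))
        assert math.isnan(auc)


class TestAggregation:
    def test_single_sample_std_zero(self):
        rep = aggregate_report([{"dice": 0.8}])
        assert rep.aggregate()["dice"] == (0.8, 0.0)

    def test_two_sample_mean_std(self):
        rep = aggregate_report([{"dice": 0.8}, {"dice": 1.0}])
        mean, std = rep.aggregate()["dice"]
        assert mean == pytest.approx(0.9) and std == pytest.approx(0.1)

    def test_identical_rows(self):
        rep = aggregate_report([{"iou": 0.7}] * 5)
        assert rep.aggregate()["iou"] == (0.7, 0.0)

    def test_table_formatting(self):
        rep = aggregate_report([{"dice": 0.9176}, {"dice": 0.9176}])
        text = rep.format_table(percent=True)
        assert "91.76" in text and "±" in text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])


class TestRoiRestriction:
    def test_metrics_respect_roi_mask(self):
        pred = np.array([[1, 0], [1, 1]], bool)
        truth = np.array([[1, 0], [0, 0]], bool)
        roi = np.array([[1, 1], [0, 0]], bool)  # evaluate top row only
        assert dice(pred, truth, roi=roi) == 1.0
        c = confusion(pred, truth, roi=roi)
        assert c.total == 2
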