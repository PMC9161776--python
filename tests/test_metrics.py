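"""Evaluation metrics: pairwise measures, matching, AJI and the detection suite.

Includes the independent brute-force oracles: a set-based AJI
implementation and exhaustive checks of the Dice--Jaccard identity.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renuseg.metrics import (
    IOU_GRID,
    aggregate_segmentation,
    aji,
    detection_suite,
    jaccard,
    match_detections,
    object_dice,
    sensitivity,
    sensitivity_from_counts,
)


def _mask(shape, boxes):
    m = np.zeros(shape, dtype=bool)
    for r0, r1, c0, c1 in boxes:
        m[r0:r1, c0:c1] = True
    return m


class TestPairwise:
    def test_identical_sets(self):
        m = _mask((20, 20), [(0, 10, 0, 10)])
        assert jaccard(m, m) == 1.0
        assert object_dice(m, m) == 1.0

    def test_disjoint_sets(self):
        a = _mask((20, 20), [(0, 5, 0, 5)])
        b = _mask((20, 20), [(10, 15, 10, 15)])
        assert jaccard(a, b) == 0.0
        assert object_dice(a, b) == 0.0

    def test_half_overlap_case(self):
        # |A| = |B| = 100, intersection 50 -> J = 1/3, D = 0.5
        a = _mask((20, 20), [(0, 10, 0, 10)])
        b = _mask((20, 20), [(5, 15, 0, 10)])
        assert jaccard(a, b) == pytest.approx(1 / 3)
        assert object_dice(a, b) == pytest.approx(0.5)

    def test_both_empty_error(self):
        z = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            jaccard(z, z)
        with pytest.raises(ValueError):
            object_dice(z, z)

    def test_dice_jaccard_identity_on_random_pairs(self, rng):
        # D = 2J / (1 + J) over 1000 random mask pairs
        for _ in range(1000):
            a = rng.random((12, 12)) > 0.6
            b = rng.random((12, 12)) > 0.6
            if not (a.any() or b.any()):
                continue
            j = jaccard(a, b)
            assert object_dice(a, b) == pytest.approx(2 * j / (1 + j))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1))
    def test_symmetry(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        if not (a.any() or b.any()):
            return
        assert jaccard(a, b) == jaccard(b, a)
        assert object_dice(a, b) == object_dice(b, a)
        assert (jaccard(a, b) == 1.0) == np.array_equal(a, b)


def _labels(shape, instances):
    lab = np.zeros(shape, dtype=np.int32)
    for k, (r0, r1, c0, c1) in enumerate(instances, start=1):
        lab[r0:r1, c0:c1] = k
    return lab


class TestMatching:
    def test_largest_overlap_wins(self):
        gt = _labels((30, 30), [(0, 10, 0, 10)])
        pred = np.zeros((30, 30), dtype=np.int32)
        pred[0:10, 0:8] = 1  # IoU 0.8
        pred[0:10, 8:10] = 2  # IoU 0.2
        m = match_detections(pred, gt, T=0.5)
        assert m.matches[1][0] == 1
        assert m.detected[1]

    def test_threshold_is_inclusive_by_default(self):
        gt = _labels((20, 20), [(0, 10, 0, 10)])
        pred = _labels((20, 20), [(0, 5, 0, 10)])  # IoU exactly 0.5
        assert match_detections(pred, gt, T=0.5).detected[1]
        assert not match_detections(pred, gt, T=0.5, strict=True).detected[1]

    def test_below_threshold_not_detected(self):
        gt = _labels((20, 20), [(0, 10, 0, 10)])
        pred = _labels((20, 20), [(0, 10, 0, 5)])  # IoU ~0.49 < 0.5? = 50/100
        m = match_detections(pred, gt, T=0.51)
        assert not m.detected[1]

    def test_no_overlap_not_detected(self):
        gt = _labels((20, 20), [(0, 5, 0, 5)])
        pred = _labels((20, 20), [(10, 15, 10, 15)])
        m = match_detections(pred, gt)
        assert not m.detected[1]
        assert m.unmatched_objects == [1]

    def test_sensitivity_counts(self):
        gt = _labels((30, 30), [(0, 10, 0, 10), (15, 25, 15, 25)])
        pred = _labels((30, 30), [(0, 10, 0, 10)])
        m = match_detections(pred, gt)
        assert sensitivity(m) == 0.5

    def test_sensitivity_nonincreasing_in_threshold(self, rng):
        gt = _labels((40, 40), [(0, 12, 0, 12), (20, 32, 5, 17), (5, 15, 25, 37)])
        pred = np.zeros((40, 40), dtype=np.int32)
        pred[2:12, 1:12] = 1
        pred[22:32, 5:15] = 2
        pred[9:15, 25:33] = 3
        sens = [sensitivity(match_detections(pred, gt, T=t))
                for t in np.linspace(0.1, 0.9, 9)]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_zero_references_error(self):
        m = match_detections(_labels((8, 8), [(0, 4, 0, 4)]),
                             np.zeros((8, 8), np.int32))
        with pytest.raises(ValueError):
            sensitivity(m)

    def test_reported_detection_ratios(self):
        # pooled-count arithmetic used for the headline sensitivities
        assert sensitivity_from_counts(4117, 4559) == pytest.approx(0.903, abs=5e-4)
        assert sensitivity_from_counts(3891, 4559) == pytest.approx(0.853, abs=5e-4)


class TestAggregateSegmentation:
    def test_perfect_matches(self):
        gt = _labels((30, 30), [(0, 10, 0, 10), (15, 25, 15, 25)])
        m = match_detections(gt, gt)
        seg = aggregate_segmentation(m, gt, gt)
        assert seg["dice_mean"] == 1.0 and seg["dice_sd"] == 0.0
        assert seg["n_pairs"] == 2

    def test_mean_of_two_pairs(self):
        gt = _labels((40, 40), [(0, 10, 0, 10), (20, 30, 20, 30)])
        pred = np.zeros((40, 40), dtype=np.int32)
        pred[0:10, 0:10] = 1  # dice 1.0
        pred[20:30, 20:25] = 2  # dice 2*50/150 = 2/3, IoU 0.5 -> included
        m = match_detections(pred, gt)
        seg = aggregate_segmentation(m, pred, gt)
        assert seg["dice_mean"] == pytest.approx((1.0 + 2 / 3) / 2)

    def test_low_iou_pair_excluded(self):
        gt = _labels((40, 40), [(0, 10, 0, 10), (20, 30, 20, 30)])
        pred = np.zeros((40, 40), dtype=np.int32)
        pred[0:10, 0:10] = 1
        pred[20:30, 20:24] = 2  # IoU 0.4 < 0.5 -> excluded from averages
        m = match_detections(pred, gt)
        seg = aggregate_segmentation(m, pred, gt)
        assert seg["n_pairs"] == 1

    def test_no_matches_reported_absent(self):
        gt = _labels((20, 20), [(0, 5, 0, 5)])
        pred = _labels((20, 20), [(10, 15, 10, 15)])
        m = match_detections(pred, gt)
        assert aggregate_segmentation(m, pred, gt) is None


# ---------------------------------------------------------------------------
# AJI with a set-based brute-force oracle
# ---------------------------------------------------------------------------


def _aji_oracle(pred, gt):
    """Independent set-based evaluation of the aggregated Jaccard index."""
    gt_sets = {k: set(zip(*np.nonzero(gt == k))) for k in range(1, gt.max() + 1)}
    pr_sets = {k: set(zip(*np.nonzero(pred == k))) for k in range(1, pred.max() + 1)}
    used, num, den = set(), 0, 0
    for g in sorted(gt_sets):
        best_p, best_iou = None, -1.0
        for p in sorted(pr_sets):
            if p in used:
                continue
            inter = len(gt_sets[g] & pr_sets[p])
            if inter == 0:
                continue
            iou = inter / len(gt_sets[g] | pr_sets[p])
            if iou > best_iou:
                best_p, best_iou = p, iou
        if best_p is None:
            den += len(gt_sets[g])
        else:
            num += len(gt_sets[g] & pr_sets[best_p])
            den += len(gt_sets[g] | pr_sets[best_p])
            used.add(best_p)
    for p, s in pr_sets.items():
        if p not in used:
            den += len(s)
    return num / den if den else 0.0


def _random_instances(rng, shape=(32, 32), n_lo=2, n_hi=4):
    lab = np.zeros(shape, dtype=np.int32)
    n = rng.integers(n_lo, n_hi + 1)
    for k in range(1, n + 1):
        r, c = rng.integers(0, shape[0] - 8, size=2)
        h, w = rng.integers(3, 9, size=2)
        lab[r : r + h, c : c + w] = k
    return lab


class TestAJI:
    def test_identical_labelings(self):
        gt = _labels((30, 30), [(0, 10, 0, 10), (15, 25, 15, 25)])
        assert aji(gt, gt) == 1.0

    def test_zero_overlap(self):
        gt = _labels((30, 30), [(0, 10, 0, 10)])
        pred = _labels((30, 30), [(20, 28, 20, 28)])
        assert aji(pred, gt) == 0.0

    def test_empty_ground_truth_error(self):
        with pytest.raises(ValueError):
            aji(_labels((8, 8), [(0, 4, 0, 4)]), np.zeros((8, 8), np.int32))

    def test_three_instance_toy_equals_oracle(self):
        gt = _labels((32, 32), [(0, 10, 0, 10), (12, 22, 12, 22), (24, 30, 2, 12)])
        pred = np.zeros((32, 32), dtype=np.int32)
        pred[1:10, 0:11] = 1
        pred[12:20, 14:22] = 2
        pred[23:30, 2:10] = 3
        pred[0:4, 20:26] = 4  # spurious object penalised in the denominator
        assert aji(pred, gt) == pytest.approx(_aji_oracle(pred, gt))

    def test_oracle_agreement_on_random_small_labelings(self, rng):
        for _ in range(60):
            gt = _random_instances(rng)
            pred = _random_instances(rng)
            if gt.max() == 0:
                continue
            assert aji(pred, gt) == pytest.approx(_aji_oracle(pred, gt))

    def test_aji_never_exceeds_mean_matched_jaccard(self, rng):
        for _ in range(20):
            gt = _random_instances(rng)
            pred = _random_instances(rng)
            if gt.max() == 0:
                continue
            m = match_detections(pred, gt, T=0.0)
            ious = [iou for _, iou in m.matches.values()]
            if not ious:
                continue
            assert aji(pred, gt) <= np.mean(ious) + 1e-12


class TestDetectionSuite:
    def test_perfect_agreement(self):
        gt = _labels((30, 30), [(0, 10, 0, 10), (15, 25, 15, 25)])
        rep = detection_suite(gt, gt)
        assert rep.map_score == 1.0
        for t in IOU_GRID:
            stats = rep.per_threshold[float(t)]
            assert stats["precision"] == stats["recall"] == stats["f1"] == 1.0

    def test_grid_is_ten_thresholds(self):
        assert len(IOU_GRID) == 10
        assert IOU_GRID[0] == 0.5 and IOU_GRID[-1] == 0.95

    def test_partial_overlap_counts_only_at_low_thresholds(self):
        gt = _labels((20, 20), [(0, 10, 0, 10)])
        pred = np.zeros((20, 20), dtype=np.int32)
        pred[0:10, 0:8] = 1  # IoU 0.8 -> counted at tau <= 0.8
        rep = detection_suite(pred, gt)
        assert rep.per_threshold[0.5]["recall"] == 1.0
        assert rep.per_threshold[0.95]["recall"] == 0.0
        expected = np.mean([1.0 if t <= 0.8 else 0.0 for t in IOU_GRID])
        assert rep.map_score == pytest.approx(expected)
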