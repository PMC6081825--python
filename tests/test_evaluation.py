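import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucseg.evaluation import (MatchResult, compute_metrics, iou,
                               match_objects, standard_error,
                               touching_separation)
from nucseg.synth import Scene, touching_pairs


def brute_force_best_tp(gt, pred, threshold=0.5):
    """Oracle: enumerate every one-to-one assignment, return max TP."""
    gt_labels = [g for g in np.unique(gt) if g > 0]
    pred_labels = [p for p in np.unique(pred) if p > 0]
    table = {}
    for g in gt_labels:
        for p in pred_labels:
            inter = ((gt == g) & (pred == p)).sum()
            union = ((gt == g) | (pred == p)).sum()
            if union:
                table[g, p] = inter / union
    best = 0
    k = min(len(gt_labels), len(pred_labels))
    for g_subset in itertools.permutations(gt_labels, k):
        tp = sum(1 for g, p in zip(g_subset, pred_labels)
                 if table.get((g, p), 0.0) > threshold)
        best = max(best, tp)
    return best


def _random_mask(rng, n_objects=5, size=32):
    mask = np.zeros((size, size), dtype=np.int32)
    for label in range(1, n_objects + 1):
        cy, cx = rng.integers(4, size - 4, 2)
        r = rng.integers(2, 5)
        yy, xx = np.mgrid[0:size, 0:size]
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = label
    return mask


class TestIou:
    def test_identical(self):
        a = np.zeros((4, 4), dtype=bool)
        a[1:3, 1:3] = True
        assert iou(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = b[3, 3] = True
        assert iou(a, b) == 0.0

    def test_enumerated_overlap(self):
        # two 2x2 squares overlapping in a 1x2 strip: 2/6 = 1/3
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0:2, 0:2] = True
        b[1:3, 0:2] = True
        assert abs(iou(a, b) - 1 / 3) < 1e-12

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2), dtype=bool), np.zeros((2, 2), dtype=bool))


class TestMatchObjects:
    def test_perfect_match(self):
        rng = np.random.default_rng(1)
        mask = _random_mask(rng, 3)
        m = match_objects(mask, mask)
        assert (m.true_positive, m.false_positive, m.false_negative) == (3, 0, 0)

    def test_iou_exactly_half_not_matched(self):
        gt = np.zeros((4, 4), dtype=np.int32)
        pred = np.zeros((4, 4), dtype=np.int32)
        gt[0, 0:2] = 1
        pred[0, 0] = 1  # IoU = 1/2 exactly; "more than 50%" is strict
        m = match_objects(gt, pred)
        assert m.true_positive == 0
        assert m.false_positive == 1 and m.false_negative == 1

    def test_greedy_equals_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            gt = _random_mask(rng)
            pred = _random_mask(rng)
            m = match_objects(gt, pred)
            assert m.true_positive == brute_force_best_tp(gt, pred)

    def test_conservation_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            gt = _random_mask(rng, n_objects=rng.integers(0, 6))
            pred = _random_mask(rng, n_objects=rng.integers(0, 6))
            m = match_objects(gt, pred)
            n_gt = len([g for g in np.unique(gt) if g > 0])
            n_pred = len([p for p in np.unique(pred) if p > 0])
            assert m.true_positive + m.false_negative == n_gt
            assert m.true_positive + m.false_positive == n_pred
            gts = [g for g, _, _ in m.pairs]
            preds = [p for _, p, _ in m.pairs]
            assert len(set(gts)) == len(gts)
            assert len(set(preds)) == len(preds)

    def test_empty_masks_allowed(self):
        empty = np.zeros((8, 8), dtype=np.int32)
        m = match_objects(empty, empty)
        assert (m.true_positive, m.false_positive, m.false_negative) == (0, 0, 0)


class TestComputeMetrics:
    def test_half_recall(self):
        p, r, f1 = compute_metrics(MatchResult(1, 0, 1, ()))
        assert (p, r) == (1.0, 0.5)
        assert abs(f1 - 2 / 3) < 1e-12

    def test_degenerate_all_zero(self):
        assert compute_metrics(MatchResult(0, 0, 0, ())) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("n", [1, 5, 100])
    def test_perfect(self, n):
        assert compute_metrics(MatchResult(n, 0, 0, ())) == (1.0, 1.0, 1.0)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=1000, deadline=None)
    def test_against_direct_formula(self, tp, fp, fn):
        p, r, f1 = compute_metrics(MatchResult(tp, fp, fn, ()))
        pe = tp / (tp + fp) if tp + fp else 0.0
        re = tp / (tp + fn) if tp + fn else 0.0
        fe = 2 * pe * re / (pe + re) if pe + re else 0.0
        assert abs(p - pe) < 1e-12
        assert abs(r - re) < 1e-12
        assert abs(f1 - fe) < 1e-12

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        gt = _random_mask(rng)
        pred = _random_mask(rng)
        m1 = compute_metrics(match_objects(gt, pred))
        m2 = compute_metrics(match_objects(pred, gt))
        assert m1[0] == pytest.approx(m2[1], abs=1e-12)
        assert m1[1] == pytest.approx(m2[0], abs=1e-12)
        assert m1[2] == pytest.approx(m2[2], abs=1e-12)


class TestStandardError:
    def test_identical_maps(self):
        x = np.random.default_rng(0).random((8, 8))
        assert standard_error(x, x) == 0.0

    def test_hand_arithmetic(self):
        out = np.array([[0.0, 0.0], [1.0, 1.0]])
        gt = np.zeros((2, 2))
        # differences (0,0,1,1): sigma = 0.5, n = 4 -> 0.25
        assert abs(standard_error(out, gt) - 0.25) < 1e-12

    def test_tiling_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(1)
        out = rng.random((8, 8))
        gt = rng.random((8, 8))
        se1 = standard_error(out, gt)
        se4 = standard_error(np.tile(out, (2, 2)), np.tile(gt, (2, 2)))
        assert abs(se4 - se1 / 2) < 1e-12

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            standard_error(np.zeros((0,)), np.zeros((0,)))


def test_match_csv_lists_unmatched_objects(tmp_path):
    from nucseg.evaluation import write_match_csv

    gt = np.zeros((10, 10), dtype=np.int32)
    gt[0:3, 0:3] = 1
    gt[5:8, 5:8] = 2
    pred = np.zeros_like(gt)
    pred[0:3, 0:3] = 1
    pred[8:10, 8:10] = 2
    path = tmp_path / "match.csv"
    write_match_csv(path, match_objects(gt, pred), gt, pred)
    lines = path.read_text().splitlines()
    assert lines[1].startswith("1,1,1.000000,TP")
    assert any(line.endswith("FN") for line in lines)
    assert any(line.endswith("FP") for line in lines)


class TestTouchingSeparation:
    @staticmethod
    def _five_pair_scene():
        mask = np.zeros((12, 50), dtype=np.int32)
        for k in range(5):  # five pairs of 4x4 squares sharing an edge
            x0 = 10 * k
            mask[2:6, x0:x0 + 4] = 2 * k + 1
            mask[6:10, x0:x0 + 4] = 2 * k + 2
        return Scene(image=None, mask=mask,
                     touching_pairs=touching_pairs(mask))

    def test_perfect_prediction(self):
        scene = self._five_pair_scene()
        sep, total, rate = touching_separation(scene, scene.mask)
        assert (sep, total, rate) == (5, 5, 1.0)

    def test_fully_merged_prediction(self):
        scene = self._five_pair_scene()
        pred = np.zeros_like(scene.mask)
        for k in range(5):  # merge each pair into one label
            pred[scene.mask == 2 * k + 1] = k + 1
            pred[scene.mask == 2 * k + 2] = k + 1
        sep, total, rate = touching_separation(scene, pred)
        assert (sep, total, rate) == (0, 5, 0.0)

    def test_three_of_five_split(self):
        scene = self._five_pair_scene()
        pred = scene.mask.copy()
        for k in (3, 4):  # merge the last two pairs
            pred[scene.mask == 2 * k + 2] = pred[scene.mask == 2 * k + 1][0]
        pred = np.unique(pred, return_inverse=True)[1].reshape(pred.shape)
        sep, total, rate = touching_separation(scene, pred)
        assert (sep, total, rate) == (3, 5, 0.6)
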