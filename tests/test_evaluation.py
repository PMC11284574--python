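import numpy as np
import pytest

import petalseg as ps
from petalseg.backends import InstanceSet, SegmentInstance
from petalseg.evaluation import labels_to_instances
from petalseg.io import LabelMask2D

from _naive_coco import naive_ap_ar


def _iset(masks_scores, shape, idx=0):
    instances = [SegmentInstance.from_mask(m, s, k + 1)
                 for k, (m, s) in enumerate(masks_scores)]
    return InstanceSet(instances, None, idx, shape)


class TestIoU:
    def test_identical_and_disjoint(self):
        a = np.zeros((5, 5), bool)
        a[1:3, 1:3] = True
        b = np.zeros((5, 5), bool)
        b[4:5, 4:5] = True
        assert ps.iou(a, a) == 1.0
        assert ps.iou(a, b) == 0.0

    def test_constructed_80_of_100(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a.reshape(-1)[:100] = True
        b.reshape(-1)[20:120] = True
        assert ps.iou(a, b) == pytest.approx(80 / 120)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.random((12, 12)) < 0.4
            b = rng.random((12, 12)) < 0.4
            inter = sum(1 for x, y in zip(a.reshape(-1), b.reshape(-1)) if x and y)
            union = sum(1 for x, y in zip(a.reshape(-1), b.reshape(-1)) if x or y)
            if union == 0:
                with pytest.warns(UserWarning):
                    assert ps.iou(a, b) == 0.0
            else:
                assert ps.iou(a, b) == inter / union

    def test_both_empty_is_zero_with_warning(self):
        z = np.zeros((3, 3), bool)
        with pytest.warns(UserWarning):
            assert ps.iou(z, z) == 0.0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            ps.iou(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestApAr:
    def test_perfect_predictions_score_one(self):
        gt = np.zeros((20, 20), dtype=int)
        gt[2:6, 2:6] = 1
        gt[10:15, 10:18] = 2
        gmask = LabelMask2D(gt)
        preds = [labels_to_instances(gmask)]
        rep = ps.ap_ar(preds, [gmask])
        assert rep.ap[0.5] == 1.0 and rep.ap["mean"] == 1.0
        assert rep.ar[0.5] == 1.0 and rep.ar["mean"] == 1.0

    def test_no_predictions_zero(self):
        gt = np.zeros((10, 10), dtype=int)
        gt[2:5, 2:5] = 1
        rep = ps.ap_ar([_iset([], (10, 10))], [LabelMask2D(gt)])
        assert rep.ap[0.5] == 0.0 and rep.ar[0.5] == 0.0

    def test_half_recall_hand_computed_pr_curve(self):
        # 2 GT, 1 exact prediction: precision 1 up to recall 0.5 ->
        # 101-point AP = 51/101
        gt = np.zeros((20, 20), dtype=int)
        gt[2:6, 2:6] = 1
        gt[10:15, 10:18] = 2
        pred = np.zeros((20, 20), bool)
        pred[2:6, 2:6] = True
        rep = ps.ap_ar([_iset([(pred, 1.0)], (20, 20))], [LabelMask2D(gt)])
        assert rep.ap[0.5] == pytest.approx(51 / 101)
        assert rep.ar[0.5] == pytest.approx(0.5)

    def test_no_gt_reports_none(self):
        rep = ps.ap_ar([_iset([], (8, 8))], [LabelMask2D(np.zeros((8, 8), dtype=int))])
        assert rep.ap[0.5] is None and rep.ar["mean"] is None

    def test_ap_non_increasing_in_threshold(self, mini_closure):
        res, gt = mini_closure
        preds = [labels_to_instances(m, s) for m, s in
                 zip(res.consensus_2d, res.group_scores)]
        thrs = ps.evaluation.COCO_IOU_THRESHOLDS
        rep = ps.ap_ar(preds, gt.masks, iou_thresholds=thrs)
        # recompute per-threshold AP individually and check monotonicity
        aps = [ps.ap_ar(preds, gt.masks, iou_thresholds=[t]).ap["mean"] for t in thrs]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        n_img = int(rng.integers(1, 4))
        shape = (24, 24)
        preds, gts, naive_preds, naive_gts = [], [], [], []
        for _ in range(n_img):
            gt = np.zeros(shape, dtype=int)
            for lab in range(1, int(rng.integers(1, 5))):
                r, c = rng.integers(0, 16, 2)
                gt[r:r + int(rng.integers(2, 8)), c:c + int(rng.integers(2, 8))] = lab
            masks_scores = []
            for _ in range(int(rng.integers(0, 7))):
                r, c = rng.integers(0, 16, 2)
                m = np.zeros(shape, bool)
                m[r:r + int(rng.integers(2, 9)), c:c + int(rng.integers(2, 9))] = True
                masks_scores.append((m, float(rng.random())))
            gmask = LabelMask2D(gt)
            preds.append(_iset(masks_scores, shape))
            gts.append(gmask)
            naive_preds.append(masks_scores)
            naive_gts.append([gt == lab for lab in np.unique(gt) if lab > 0])
        for thr in (0.5, 0.75):
            rep = ps.ap_ar(preds, gts, iou_thresholds=[thr])
            ap, ar = naive_ap_ar(naive_preds, naive_gts, thr)
            if ap is None:
                assert rep.ap["mean"] is None
            else:
                assert rep.ap["mean"] == pytest.approx(ap, abs=1e-6)
                assert rep.ar["mean"] == pytest.approx(ar, abs=1e-6)


class TestMape:
    def test_exact_match_zero(self):
        assert ps.mape_area([ps.AreaMatch(100, 100), ps.AreaMatch(7, 7)]) == 0.0

    def test_example_ten_percent(self):
        matches = [ps.AreaMatch(110, 100), ps.AreaMatch(180, 200)]
        assert ps.mape_area(matches) == pytest.approx(10.0)

    def test_single_petal_fifty_percent(self):
        assert ps.mape_area([ps.AreaMatch(25, 50)]) == pytest.approx(50.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(10, 100, 8)
        e = g * rng.uniform(0.8, 1.2, 8)
        base = ps.mape_area([ps.AreaMatch(x, y) for x, y in zip(e, g)])
        scaled = ps.mape_area([ps.AreaMatch(3.7 * x, 3.7 * y) for x, y in zip(e, g)])
        assert scaled == pytest.approx(base)

    def test_empty_and_zero_gt_raise(self):
        with pytest.raises(ValueError):
            ps.mape_area([])
        with pytest.raises(ValueError):
            ps.AreaMatch(10, 0)


class TestAreaStats:
    def test_physical_pixel_area_conversion(self):
        # one petal of 1000 px at 46.252 um/px -> 1000 * 2139.2 um^2 = 2.1392 mm^2
        labels = np.zeros((40, 40), dtype=int)
        labels.reshape(-1)[:1000] = 1
        areas, mean, _ = ps.area_stats([LabelMask2D(labels)], 46.252)
        assert mean == pytest.approx(2.1392, rel=1e-4)

    def test_one_px_petal_at_one_mm_pixel(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = 1
        areas, mean, _ = ps.area_stats([LabelMask2D(labels)], 1000.0)
        assert mean == pytest.approx(1.0)

    def test_no_petals_raise(self):
        with pytest.raises(ValueError):
            ps.area_stats([LabelMask2D(np.zeros((4, 4), dtype=int))], 46.252)

    def test_sample_variance(self):
        labels = np.zeros((10, 10), dtype=int)
        labels.reshape(-1)[:10] = 1
        labels.reshape(-1)[10:40] = 2
        areas, mean, var = ps.area_stats([LabelMask2D(labels)], 1000.0)
        np.testing.assert_allclose(sorted(areas), [10.0, 30.0])
        assert var == pytest.approx(np.var([10.0, 30.0], ddof=1))
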