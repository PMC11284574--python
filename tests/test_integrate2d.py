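import numpy as np
import pytest

import petalseg as ps
from petalseg.backends import InstanceSet, SegmentInstance
from petalseg.cropping import CropFrame
from petalseg.integrate2d import (merge_by_iou, project_to_slice, rasterize_consensus,
                                  remove_errors)

SHAPE = (40, 60)
FULL = np.arange(SHAPE[0] * SHAPE[1], dtype=np.int64)


def _inst(mask, iid, score=1.0, theta=None):
    return SegmentInstance.from_mask(mask, score, iid, theta)


def _set(instances, theta):
    for i in instances:
        i.source_theta_deg = theta
    return InstanceSet(instances, None, 0, SHAPE, disjoint=True)


def _bar(r0, r1, c0, c1):
    m = np.zeros(SHAPE, bool)
    m[r0:r1, c0:c1] = True
    return m


@pytest.fixture()
def fig9_fixture():
    """Two adjacent crops disagreeing about the division of one region.

    Crop A sees two masks (S11, S12); crop B sees S21 matching S11 and two
    masks S22, S23 that together cover S12's region.  The coarse S12 is the
    one the divided-is-correct rule must delete.
    """
    s11 = _bar(5, 10, 5, 55)
    s12 = _bar(20, 25, 5, 55)
    s21 = _bar(5, 10, 5, 55)
    s22 = _bar(20, 25, 5, 28)
    s23 = _bar(20, 25, 32, 55)
    sets = {
        0.0: _set([_inst(s11, 1), _inst(s12, 2)], 0.0),
        1.0: _set([_inst(s21, 1), _inst(s22, 2), _inst(s23, 3)], 1.0),
    }
    footprints = {0.0: FULL, 1.0: FULL}
    return sets, footprints


class TestRemoveErrors:
    def test_fig9_deletes_exactly_the_coarse_mask(self, fig9_fixture):
        sets, footprints = fig9_fixture
        filtered, log = remove_errors(sets, footprints, min_overlap_px=5)
        assert [i.instance_id for i in filtered[0.0].instances] == [1]
        assert [i.instance_id for i in filtered[1.0].instances] == [1, 2, 3]
        assert len(log) == 1
        assert log[0]["theta_deg"] == 0.0 and log[0]["instance_id"] == 2
        assert sorted(log[0]["partners"]) == [2, 3]

    def test_one_to_one_overlaps_keep_everything(self):
        sets = {
            0.0: _set([_inst(_bar(5, 10, 5, 55), 1), _inst(_bar(20, 25, 5, 55), 2)], 0.0),
            1.0: _set([_inst(_bar(5, 10, 6, 56), 1), _inst(_bar(20, 25, 6, 56), 2)], 1.0),
        }
        filtered, log = remove_errors(sets, {0.0: FULL, 1.0: FULL})
        assert log == []
        assert all(len(s.instances) == 2 for s in filtered.values())

    def test_sub_threshold_sliver_not_counted_as_division(self):
        # the second partner only grazes the mask by 4 px (< min_overlap 5)
        coarse = _bar(20, 25, 5, 55)
        sets = {
            0.0: _set([_inst(coarse, 1)], 0.0),
            1.0: _set([_inst(_bar(20, 25, 5, 40), 1), _inst(_bar(21, 25, 54, 55), 2)], 1.0),
        }
        filtered, log = remove_errors(sets, {0.0: FULL, 1.0: FULL}, min_overlap_px=5)
        assert log == []
        assert len(filtered[0.0].instances) == 1

    def test_oracle_split_on_one_angle_removes_spanning_counterparts(self, small_phantom):
        vol, gt = small_phantom
        center = (79.5, 79.5)
        thetas = [0.0, 2.0, 4.0]
        sets = {}
        geoms = {}
        for theta in thetas:
            frame = CropFrame(center, theta, 260, 24)
            crop = ps.extract_crop(vol.slices[0], frame, 20.0, 5.0, rng_seed=0)
            backend = (ps.OracleBackend(gt.masks, p_split=1.0, rng_seed=5)
                       if theta == 2.0 else ps.OracleBackend(gt.masks))
            sets[theta] = backend.segment(crop)
            from petalseg.cropping import _band_geometry
            geoms[theta] = _band_geometry(frame, vol.shape)
        footprints = {t: g[0] for t, g in geoms.items()}
        slice_sets = project_to_slice(sets, geoms, vol.shape)
        filtered, log = remove_errors(slice_sets, footprints, min_overlap_px=5)
        assert log  # the unsplit neighbours spanning both halves are removed
        assert all(entry["theta_deg"] in (0.0, 4.0) for entry in log)
        assert all(len(entry["partners"]) >= 2 for entry in log)


class TestMergeByIou:
    def test_identical_masks_across_angles_form_one_group(self):
        mask = _bar(10, 18, 10, 50)
        thetas = [float(t) for t in range(0, 360, 45)]
        sets = {t: _set([_inst(mask.copy(), 1)], t) for t in thetas}
        footprints = {t: FULL for t in thetas}
        groups = merge_by_iou(sets, footprints)
        assert len(groups) == 1
        assert len(groups[0].members) == len(thetas)

    @pytest.mark.parametrize("inter,expected_groups", [(79, 2), (80, 1)])
    def test_threshold_boundary(self, inter, expected_groups):
        # |A| = |B| = 90; IoU = inter / (180 - inter): 79 -> 0.782, 80 -> 0.8
        a = np.zeros(SHAPE, bool)
        b = np.zeros(SHAPE, bool)
        a.reshape(-1)[:90] = True
        b.reshape(-1)[90 - inter:180 - inter] = True
        sets = {0.0: _set([_inst(a, 1)], 0.0), 1.0: _set([_inst(b, 1)], 1.0)}
        groups = merge_by_iou(sets, {0.0: FULL, 1.0: FULL}, iou_threshold=0.8)
        assert len(groups) == expected_groups

    def test_partition_property(self, small_phantom):
        vol, gt = small_phantom
        sets, footprints = _phantom_slice_sets(vol, gt, [0.0, 2.0, 4.0, 6.0])
        groups = merge_by_iou(sets, footprints)
        refs = [ref for g in groups for ref in g.member_refs]
        assert len(refs) == len(set(refs))
        total = sum(len(s.instances) for s in sets.values())
        assert len(refs) == total

    def test_raising_threshold_never_decreases_group_count(self, small_phantom):
        vol, gt = small_phantom
        sets, footprints = _phantom_slice_sets(vol, gt, [0.0, 2.0, 4.0])
        counts = [len(merge_by_iou(sets, footprints, iou_threshold=t))
                  for t in (0.5, 0.8, 0.95)]
        assert counts == sorted(counts)

    def test_group_structure_invariant_to_set_ordering(self, small_phantom):
        vol, gt = small_phantom
        sets, footprints = _phantom_slice_sets(vol, gt, [0.0, 2.0, 4.0, 6.0])
        groups_fwd = merge_by_iou(sets, footprints)
        shuffled = dict(reversed(list(sets.items())))
        groups_rev = merge_by_iou(shuffled, footprints)
        assert ([g.member_refs for g in groups_fwd]
                == [g.member_refs for g in groups_rev])

    def test_zero_noise_group_count_matches_gt_petals(self, small_phantom):
        # every group of crop masks corresponds to (a copy chain of) one petal
        vol, gt = small_phantom
        thetas = [float(t) for t in range(0, 360, 2)]
        sets, footprints = _phantom_slice_sets(vol, gt, thetas)
        groups = merge_by_iou(sets, footprints)
        mask = rasterize_consensus(groups, vol.shape, min_region_px=20)
        got = ps.ap_ar([_labels_to_scored(mask)], [gt.masks[0]])
        assert got.ap[0.5] == 1.0


def _labels_to_scored(mask):
    from petalseg.evaluation import labels_to_instances

    return labels_to_instances(mask)


def _phantom_slice_sets(vol, gt, thetas):
    from petalseg.cropping import _band_geometry

    center = (79.5, 79.5)
    sets = {}
    geoms = {}
    backend = ps.OracleBackend(gt.masks)
    for theta in thetas:
        frame = CropFrame(center, theta, 260, 24)
        crop = ps.extract_crop(vol.slices[0], frame, 20.0, 5.0, rng_seed=0)
        sets[theta] = backend.segment(crop)
        geoms[theta] = _band_geometry(frame, vol.shape)
    footprints = {t: g[0] for t, g in geoms.items()}
    return project_to_slice(sets, geoms, vol.shape), footprints


class TestRasterizeConsensus:
    def test_single_member_group_is_its_mask(self):
        mask = _bar(3, 9, 4, 30)
        g = ps.PetalGroup(1, [(0.0, 1)], [_inst(mask, 1, theta=0.0)], SHAPE)
        out = rasterize_consensus([g], SHAPE)
        np.testing.assert_array_equal(out.labels > 0, mask)
        assert set(np.unique(out.labels)) == {0, 1}

    def test_majority_wins_overlap(self):
        overlap = _bar(10, 11, 10, 20)  # 10 px
        a_mask = _bar(10, 15, 10, 20)
        b_mask = _bar(5, 11, 10, 20)
        ga = ps.PetalGroup(1, [], [_inst(a_mask, i, theta=float(i)) for i in range(3)], SHAPE)
        gb = ps.PetalGroup(2, [], [_inst(b_mask, 1, theta=0.0)], SHAPE)
        out = rasterize_consensus([ga, gb], SHAPE)
        assert (out.labels[overlap] == 1).all()

    def test_empty_group_list_all_zero(self):
        out = rasterize_consensus([], SHAPE)
        assert not out.labels.any()

    def test_region_floor_clears_small_labels(self):
        g1 = ps.PetalGroup(1, [], [_inst(_bar(0, 10, 0, 10), 1, theta=0.0)], SHAPE)
        g2 = ps.PetalGroup(2, [], [_inst(_bar(30, 31, 0, 3), 1, theta=0.0)], SHAPE)
        out = rasterize_consensus([g1, g2], SHAPE, min_region_px=20)
        assert set(np.unique(out.labels)) == {0, 1}
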