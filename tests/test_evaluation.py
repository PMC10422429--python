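import numpy as np
import pytest

from beetraffic.alignment import AlignmentParams
from beetraffic.detector import Detection
from beetraffic.evaluation import (ConfusionCounts, EvalCategory,
                                   GroundTruthEvent, MetricSet, MotionState,
                                   classify_event, compute_metrics,
                                   evaluate_frame, match_detections_to_truth,
                                   mean_metrics, pool_counts, tally)
from beetraffic.motion_detect import MotionRegion
from beetraffic.published import CONFUSION_COUNTS, PUBLISHED_METRICS

from .oracles import best_matching_exhaustive


def _region(x, y, w=20, h=20):
    contour = np.array([[x, y], [x + w - 1, y], [x + w - 1, y + h - 1],
                        [x, y + h - 1]], float)
    return MotionRegion(x, y, w, h, contour, float((w - 1) * (h - 1)))


def _gt(x1, y1, x2, y2, state):
    return GroundTruthEvent(1, (x1, y1, x2, y2), state)


DET = Detection(100, 100, 140, 130, 0.9)          # center (120, 115)
GT_ON_DET = _gt(98, 99, 141, 132, MotionState.FLYING)
REGION_ON_DET = _region(110, 105)                  # overlaps, center close
REGION_FAR = _region(400, 400)                     # C1 fails
REGION_NEAR_NO_OVERLAP = Detection  # placeholder, unused


class TestClassifyEvent:
    def test_flying_with_confirming_motion(self):
        cat = classify_event(GT_ON_DET, DET, REGION_ON_DET)
        assert cat is EvalCategory.BTP_BFLMTP

    def test_crawling_with_confirming_motion(self):
        gt = _gt(98, 99, 141, 132, MotionState.CRAWLING)
        assert classify_event(gt, DET, REGION_ON_DET) is EvalCategory.BTP_BCRMTP

    def test_stationary_without_motion(self):
        gt = _gt(98, 99, 141, 132, MotionState.STATIONARY)
        assert classify_event(gt, DET, None) is EvalCategory.BTP_BMTN
        assert classify_event(gt, DET, REGION_FAR) is EvalCategory.BTP_BMTN

    def test_moving_but_motion_missed(self):
        assert classify_event(GT_ON_DET, DET, None) is EvalCategory.BTP_BMFN

    def test_missed_flying_bee_with_and_without_motion(self):
        region = _region(95, 95)  # overlaps the gt box, center nearby
        assert classify_event(GT_ON_DET, None, region) is \
            EvalCategory.BFN_BFLMTP
        assert classify_event(GT_ON_DET, None, None) is \
            EvalCategory.BFN_BFLMFN

    def test_detection_without_truth_is_false_positive(self):
        assert classify_event(None, DET, None) is EvalCategory.BFP
        assert classify_event(None, DET, REGION_ON_DET) is EvalCategory.BFP

    def test_c2_requires_positive_intersection(self):
        # region center within 50 px of the detection center but the
        # rectangles do not overlap → motion does not confirm
        region = _region(141, 131, 10, 10)  # corner-adjacent, zero overlap
        assert classify_event(GT_ON_DET, DET, region) is EvalCategory.BTP_BMFN

    def test_missed_nonflying_bee_is_no_event(self):
        gt = _gt(98, 99, 141, 132, MotionState.STATIONARY)
        assert classify_event(gt, None, None) is None

    def test_requires_gt_or_detection(self):
        with pytest.raises(ValueError):
            classify_event(None, None, None)

    def test_every_configuration_maps_to_one_category(self):
        states = list(MotionState)
        regions = [None, REGION_ON_DET, REGION_FAR]
        for state in states:
            gt = _gt(98, 99, 141, 132, state)
            for det in (None, DET):
                for region in regions:
                    if det is None and state is not MotionState.FLYING:
                        continue  # out-of-taxonomy by design
                    cat = classify_event(gt, det, region)
                    assert isinstance(cat, EvalCategory)


class TestMatching:
    def test_identical_sets_match_perfectly(self):
        gts = [_gt(i * 50, 0, i * 50 + 20, 20, MotionState.FLYING)
               for i in range(5)]
        dets = [Detection(*g.box, 0.9) for g in gts]
        pairs, ug, ud = match_detections_to_truth(dets, gts)
        assert sorted(pairs) == [(i, i) for i in range(5)]
        assert ug == [] and ud == []

    def test_disjoint_sets_match_nothing(self):
        gts = [_gt(0, 0, 10, 10, MotionState.FLYING)]
        dets = [Detection(500, 500, 520, 520, 0.9)]
        pairs, ug, ud = match_detections_to_truth(dets, gts)
        assert pairs == [] and ug == [0] and ud == [0]

    def test_matches_exhaustive_assignment_on_planted_scenes(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            gts, dets = [], []
            for i in range(n):
                x = i * 120.0
                gts.append(_gt(x, 0, x + 40, 40, MotionState.FLYING))
                if rng.random() < 0.7:  # planted overlap with its own gt only
                    jx, jy = rng.uniform(-8, 8, 2)
                    dets.append(Detection(x + jx, jy, x + 40 + jx, 40 + jy, .9))
            if rng.random() < 0.5:
                dets.append(Detection(5000, 5000, 5020, 5020, .9))
            pairs, _, _ = match_detections_to_truth(dets, gts)
            expected = best_matching_exhaustive([g.box for g in gts],
                                                [d.box for d in dets])
            assert sorted(pairs) == sorted(expected)


class TestTallyAndMetrics:
    def test_category_to_count_mapping(self):
        assert tally([EvalCategory.BTP_BFLMTP] * 4) == ConfusionCounts(4, 0, 0)
        assert tally([EvalCategory.BFN_BFLMTP, EvalCategory.BFN_BFLMFN,
                      EvalCategory.BFP]) == ConfusionCounts(0, 2, 1)

    def test_random_multiset_tally_is_histogram(self):
        rng = np.random.default_rng(5)
        cats = [list(EvalCategory)[i]
                for i in rng.integers(0, 7, 200)]
        c = tally(cats, nf=30, nv=1)
        from beetraffic.evaluation import FN_CATEGORIES, TP_CATEGORIES
        assert c.TP == sum(cats.count(x) for x in TP_CATEGORIES)
        assert c.FN == sum(cats.count(x) for x in FN_CATEGORIES)
        assert c.FP == cats.count(EvalCategory.BFP)
        assert (c.NF, c.NV) == (30, 1)

    def test_perfect_counts_give_unit_metrics(self):
        m = compute_metrics(ConfusionCounts(17, 0, 0))
        assert m.as_tuple() == (1.0, 1.0, 1.0, 1.0)

    @pytest.mark.parametrize("tp,fn,fp,expected", [
        (377, 581, 0, (0.39, 1.00, 0.56, 0.39)),
        (250, 3836, 24, (0.06, 0.91, 0.11, 0.06)),
    ])
    def test_published_rows_reproduce(self, tp, fn, fp, expected):
        m = compute_metrics(ConfusionCounts(tp, fn, fp)).rounded()
        assert m.as_tuple() == expected

    def test_undefined_metrics_warn_and_are_nan(self):
        with pytest.warns(RuntimeWarning):
            m = compute_metrics(ConfusionCounts(0, 0, 0))
        assert np.isnan(m.precision_as_printed)

    def test_pool_counts_sums_not_means(self):
        pooled = pool_counts([ConfusionCounts(377, 581, 0, 1800, 60),
                              ConfusionCounts(833, 2577, 0, 1800, 60)])
        assert (pooled.TP, pooled.FN, pooled.FP) == (1210, 3158, 0)
        m = compute_metrics(pooled).rounded()
        assert m.precision_as_printed == 0.28  # != mean(0.39, 0.24) = 0.315
        mm = mean_metrics([ConfusionCounts(377, 581, 0),
                           ConfusionCounts(833, 2577, 0)])
        assert mm.precision_as_printed == pytest.approx(0.3189, abs=1e-3)

    def test_pool_single_stratum_identity_and_random_sums(self):
        c = ConfusionCounts(3, 4, 5, 6, 7)
        assert pool_counts([c]) == c
        rng = np.random.default_rng(8)
        strata = [ConfusionCounts(*rng.integers(0, 100, 3)) for _ in range(6)]
        pooled = pool_counts(strata)
        assert pooled.TP == sum(s.TP for s in strata)
        assert pooled.FN == sum(s.FN for s in strata)
        assert pooled.FP == sum(s.FP for s in strata)


class TestEvaluateFrame:
    def test_ignore_mask_excludes_detections(self):
        det = Detection(10, 10, 30, 30, 0.9)
        cats = evaluate_frame([], [det], [], ignore_boxes=[(0, 0, 20, 20)])
        assert cats == []
        cats2 = evaluate_frame([], [det], [])
        assert cats2 == [EvalCategory.BFP]

    def test_mixed_frame(self):
        gts = [GT_ON_DET,
               _gt(300, 300, 340, 330, MotionState.FLYING)]  # undetected
        dets = [DET, Detection(600, 600, 640, 630, 0.9)]      # second is FP
        regions = [REGION_ON_DET, _region(295, 295)]
        cats = evaluate_frame(gts, dets, regions)
        assert sorted(c.value for c in cats) == \
            ["BFN_BFLMTP", "BFP", "BTP_BFLMTP"]
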