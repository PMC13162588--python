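"""Evaluator checked against analytic PR cases and a brute-force
re-implementation on randomized instances."""

import numpy as np
import pytest

from cattleact import NORMAL, PROTECTIVE
from cattleact.data_ava import AvaRecord
from cattleact.evaluation import (
    MatchResult, ResultRecord, average_precision, evaluate_detections, iou,
    match_detections, mean_ap, read_result_csv, write_result_csv,
)


def gt(video, t, box, action=NORMAL):
    return AvaRecord(video, t, box, action, 0)


def det(video, t, box, action=NORMAL, score=0.9):
    return ResultRecord(video, t, box, action, score)


# --------------------------------------------------------------- brute force
def brute_force_ap(dets, gts, iou_thr):
    """Independent naive evaluator: loop-based greedy matching then direct
    envelope integration over every operating point."""
    dets = sorted(dets, key=lambda d: -d.score)
    claimed = [False] * len(gts)
    flags = []
    for d in dets:
        best, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if claimed[j] or g.video_id != d.video_id \
                    or g.timestamp != d.timestamp:
                continue
            v = iou(d.box, g.box)
            if v > best:
                best, best_j = v, j
        if best_j >= 0 and best >= iou_thr:
            claimed[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    n_gt = len(gts)
    if n_gt == 0:
        return None
    points = []
    tp = fp = 0
    for f in flags:
        tp, fp = tp + f, fp + (not f)
        points.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _) in enumerate(points):
        if r > prev_r:
            best_p = max(p for rr, p in points[i:])
            ap += (r - prev_r) * best_p
            prev_r = r
    return ap


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0.1, 0.1, 0.6, 0.6), (0.1, 0.1, 0.6, 0.6)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 0.3, 0.3), (0.5, 0.5, 0.9, 0.9)) == 0.0

    def test_hand_geometry(self):
        assert iou((0, 0, 1, 1), (0.5, 0, 1.5, 1)) == pytest.approx(1 / 3)

    def test_degenerate_box_scores_zero(self):
        assert iou((0.2, 0.2, 0.2, 0.8), (0, 0, 1, 1)) == 0.0


class TestMatching:
    def test_exact_detections_are_all_tp(self):
        gts = [gt("v", 0, (0.1, 0.1, 0.5, 0.5)), gt("v", 1, (0.2, 0.2, 0.8, 0.8))]
        dets = [det(g.video_id, g.timestamp, g.box) for g in gts]
        m = match_detections(dets, gts)
        assert m.tp_flags.all() and not m.fp_flags.any()

    def test_single_match_rule_keeps_higher_confidence(self):
        gts = [gt("v", 0, (0.1, 0.1, 0.5, 0.5))]
        dets = [det("v", 0, (0.1, 0.1, 0.5, 0.5), score=0.6),
                det("v", 0, (0.12, 0.1, 0.5, 0.5), score=0.9)]
        m = match_detections(dets, gts)
        # confidence order: the 0.9 det matches, the 0.6 det is the FP
        assert m.tp_flags.tolist() == [True, False]

    def test_cross_class_matching_forbidden(self):
        gts = [gt("v", 0, (0.1, 0.1, 0.5, 0.5), NORMAL)]
        dets = [det("v", 0, (0.1, 0.1, 0.5, 0.5), PROTECTIVE)]
        m = match_detections(dets, gts, action_id=PROTECTIVE)
        assert m.fp_flags.all() and m.n_gt == 0

    def test_mixed_class_input_without_filter_rejected(self):
        gts = [gt("v", 0, (0.1, 0.1, 0.5, 0.5), NORMAL),
               gt("v", 0, (0.6, 0.6, 0.9, 0.9), PROTECTIVE)]
        with pytest.raises(ValueError):
            match_detections([], gts)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        m = MatchResult(np.array([True, True]), np.array([False, False]), 2)
        assert average_precision(m) == pytest.approx(1.0)

    def test_all_false_positives(self):
        m = MatchResult(np.array([False, False]), np.array([True, True]), 2)
        assert average_precision(m) == pytest.approx(0.0)

    def test_tp_fp_tp_hand_curve(self):
        m = MatchResult(np.array([True, False, True]),
                        np.array([False, True, False]), 2)
        assert average_precision(m) == pytest.approx(0.5 + 0.5 * 2 / 3, abs=1e-9)

    def test_no_ground_truth_is_undefined(self):
        m = MatchResult(np.array([False]), np.array([True]), 0)
        with pytest.warns(UserWarning):
            assert average_precision(m) is None

    def test_trailing_fp_never_raises_ap(self):
        base = MatchResult(np.array([True, True]), np.array([False, False]), 3)
        worse = MatchResult(np.array([True, True, False]),
                            np.array([False, False, True]), 3)
        assert average_precision(worse) <= average_precision(base)

    def test_leading_tp_never_lowers_ap(self):
        base = MatchResult(np.array([True, False]), np.array([False, True]), 3)
        better = MatchResult(np.array([True, True, False]),
                             np.array([False, False, True]), 3)
        assert average_precision(better) >= average_precision(base)


class TestMeanAp:
    def test_two_class_mean(self):
        assert mean_ap({NORMAL: 0.8, PROTECTIVE: 0.6}) == pytest.approx(0.7)

    def test_single_defined_class(self):
        assert mean_ap({NORMAL: 0.8, PROTECTIVE: None}) == pytest.approx(0.8)

    def test_nothing_defined_rejected(self):
        with pytest.raises(ValueError):
            mean_ap({NORMAL: None})


class TestBruteForceEquivalence:
    def random_instance(self, rng):
        gts, dets = [], []
        for _ in range(int(rng.integers(0, 25))):
            x1, y1 = rng.uniform(0, 0.6, 2)
            w, h = rng.uniform(0.05, 0.4, 2)
            gts.append(gt(f"v{rng.integers(2)}", int(rng.integers(3)),
                          (x1, y1, min(x1 + w, 1), min(y1 + h, 1)),
                          int(rng.choice([NORMAL, PROTECTIVE]))))
        for _ in range(int(rng.integers(0, 25))):
            if gts and rng.random() < 0.6:  # perturbations of real boxes
                g = gts[rng.integers(len(gts))]
                jitter = rng.normal(0, 0.04, 4)
                x1, y1, x2, y2 = np.clip(np.array(g.box) + jitter, 0, 1)
                box = (min(x1, x2 - 1e-3), min(y1, y2 - 1e-3), x2, y2)
                dets.append(det(g.video_id, g.timestamp, box, g.action_id,
                                float(rng.uniform(0.1, 1))))
            else:
                x1, y1 = rng.uniform(0, 0.6, 2)
                w, h = rng.uniform(0.05, 0.4, 2)
                dets.append(det(f"v{rng.integers(2)}", int(rng.integers(3)),
                                (x1, y1, min(x1 + w, 1), min(y1 + h, 1)),
                                int(rng.choice([NORMAL, PROTECTIVE])),
                                float(rng.uniform(0.1, 1))))
        return dets, gts

    def test_pipeline_equals_brute_force_on_100_random_instances(self):
        rng = np.random.default_rng(42)
        compared = 0
        for _ in range(100):
            dets, gts = self.random_instance(rng)
            for c in (NORMAL, PROTECTIVE):
                cd = [d for d in dets if d.action_id == c]
                cg = [g for g in gts if g.action_id == c]
                expected = brute_force_ap(cd, cg, 0.5)
                if expected is None:
                    continue
                got = average_precision(match_detections(dets, gts, 0.5, c))
                assert got == pytest.approx(expected, abs=1e-12)
                compared += 1
        assert compared > 100  # the comparison actually exercised many cases

    def test_full_report_matches_brute_force_mean(self):
        rng = np.random.default_rng(7)
        dets, gts = self.random_instance(rng)
        while not gts:
            dets, gts = self.random_instance(rng)
        report = evaluate_detections(dets, gts, 0.5)
        aps = []
        for c in sorted({g.action_id for g in gts}):
            aps.append(brute_force_ap([d for d in dets if d.action_id == c],
                                      [g for g in gts if g.action_id == c],
                                      0.5))
        assert report["map"] == pytest.approx(np.mean(aps), abs=1e-12)


class TestResultCsv:
    def test_roundtrip(self, tmp_path):
        records = [det("v1", 0, (0.1, 0.2, 0.5, 0.6), NORMAL, 0.75),
                   det("v2", 3, (0.0, 0.0, 1.0, 1.0), PROTECTIVE, 0.5)]
        p = tmp_path / "results.csv"
        write_result_csv(records, p)
        back = read_result_csv(p)
        assert len(back) == 2
        for a, b in zip(records, back):
            assert a.video_id == b.video_id and a.timestamp == b.timestamp
            np.testing.assert_allclose(a.box, b.box, atol=1e-6)
            assert a.action_id == b.action_id
            assert a.score == pytest.approx(b.score, abs=1e-6)
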