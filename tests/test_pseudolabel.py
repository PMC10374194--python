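"""Adaptive thresholding, self-learning loop, matching, PR/AP evaluator."""

from __future__ import annotations

import numpy as np
import pytest

from phenosynth import fixtures as fx
from phenosynth import pseudolabel as pl
from phenosynth.pseudolabel import ScoredBox


def brute_force_threshold(scores, grid_step=0.01):
    """Independent exhaustive sweep of the between-class variance."""
    scores = np.asarray(scores, float)
    best_t, best_v = None, -1.0
    t = grid_step
    while t < 1.0 - 1e-12:
        lo = scores[scores < t]
        hi = scores[scores >= t]
        if lo.size and hi.size:
            v = (lo.size / scores.size) * (hi.size / scores.size) * (
                lo.mean() - hi.mean()
            ) ** 2
        else:
            v = 0.0
        if v > best_v + 1e-15:
            best_v, best_t = v, t
        t += grid_step
    return best_t, best_v


class TestAdaptiveThreshold:
    def test_two_point_mixture_closed_form(self):
        scores = [0.1] * 100 + [0.9] * 100
        report = pl.select_adaptive_threshold(scores, grid_step=0.01)
        assert 0.1 < report.chosen < 0.9
        assert report.variance_curve.max() == pytest.approx(
            0.25 * 0.8**2, abs=1e-9
        )

    def test_degenerate_identical_scores(self):
        report = pl.select_adaptive_threshold([0.5] * 10)
        assert report.degenerate

    def test_matches_exhaustive_sweep_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            scores = rng.uniform(0.01, 0.99, size=n)
            report = pl.select_adaptive_threshold(scores, grid_step=0.01)
            t_oracle, v_oracle = brute_force_threshold(scores, 0.01)
            assert report.chosen == pytest.approx(t_oracle, abs=1e-9)
            assert report.variance_curve.max() == pytest.approx(v_oracle, abs=1e-12)

    def test_tie_breaks_toward_lower_threshold(self):
        # flat plateau between the two mass points: the first (lowest)
        # candidate on the plateau must be chosen
        report = pl.select_adaptive_threshold([0.2] * 5 + [0.8] * 5, grid_step=0.1)
        assert report.chosen == pytest.approx(0.3)


class TestFilter:
    def test_threshold_zero_keeps_all_and_one_keeps_perfect(self):
        boxes = [
            ScoredBox("i", (0, 0, 10, 10), s) for s in (0.2, 0.5, 1.0, 0.8)
        ]
        assert pl.filter_pseudo_labels(boxes, 0.0) == boxes
        kept = pl.filter_pseudo_labels(boxes, 1.0)
        assert [b.score for b in kept] == [1.0]

    def test_mixed_set_count(self):
        rng = np.random.default_rng(4)
        boxes = [
            ScoredBox("i", (0, 0, 5, 5), float(s))
            for s in rng.uniform(0, 1, 100)
        ]
        kept = pl.filter_pseudo_labels(boxes, 0.6)
        assert len(kept) == sum(b.score >= 0.6 for b in boxes)


def _grid_truth(n_images=20, boxes_per=8, seed=0):
    rng = np.random.default_rng(seed)
    truth = []
    for i in range(n_images):
        for _ in range(boxes_per):
            w, h = rng.uniform(30, 60, 2)
            truth.append(
                ScoredBox(
                    f"img_{i:03d}",
                    (float(rng.uniform(0, 450)), float(rng.uniform(0, 450)),
                     float(w), float(h)),
                    1.0,
                )
            )
    return truth


class TestSelfLearningLoop:
    def test_false_boxes_filtered_after_one_round(self):
        truth = _grid_truth(seed=1)
        detector = fx.MockDetector(
            truth, score_high=0.9, score_low=0.3, fp_rate=0.3, miss_rate=0.0,
            score_spread=0.05,
        )
        images = sorted({t.image_ref for t in truth})
        result = pl.self_learning_loop(detector, images, truth, images, rounds=1)
        retained = result.labels
        raw = detector.infer(images, detector.train(images, truth, None), seed=0)
        n_false_raw = sum(b.origin == "false" for b in raw)
        n_false_kept = sum(b.origin == "false" for b in retained)
        assert n_false_raw > 0
        assert n_false_kept <= 0.05 * n_false_raw

    def test_perfect_detector_round_trip(self):
        truth = _grid_truth(n_images=5, seed=2)
        detector = fx.MockDetector(
            truth, score_high=0.9, score_low=0.1, fp_rate=0.0, miss_rate=0.0,
            score_spread=0.0,
        )
        images = sorted({t.image_ref for t in truth})
        result = pl.self_learning_loop(detector, images, truth, images, rounds=1)
        assert len(result.labels) == len(truth)
        got = sorted((b.image_ref, b.bbox) for b in result.labels)
        want = sorted((t.image_ref, t.bbox) for t in truth)
        assert got == want

    def test_round_reports_match_retained_counts(self):
        truth = _grid_truth(seed=3)
        detector = fx.MockDetector(truth, fp_rate=0.2)
        images = sorted({t.image_ref for t in truth})
        result = pl.self_learning_loop(detector, images, truth, images, rounds=3)
        assert len(result.rounds) == 3
        assert result.rounds[-1].n_retained == len(result.labels)
        for r in result.rounds:
            assert r.n_retained <= r.n_detections

    def test_precision_strictly_improves_round0_to_round1(self):
        for seed in range(10):
            truth = _grid_truth(n_images=30, boxes_per=8, seed=100 + seed)
            detector = fx.MockDetector(
                truth, score_high=0.8, score_low=0.5, fp_rate=0.3,
                miss_rate=0.0, score_spread=0.12,
            )
            images = sorted({t.image_ref for t in truth})
            state = detector.train(images, truth, None)
            precisions = []
            for r in range(2):
                dets = detector.infer(images, state, seed=seed + r)
                t = pl.select_adaptive_threshold([b.score for b in dets]).chosen
                kept = pl.filter_pseudo_labels(dets, t)
                precisions.append(
                    sum(b.origin == "truth" for b in kept) / len(kept)
                )
                state = detector.train(images, kept, state)
            assert precisions[1] > precisions[0]


class TestMatching:
    def test_identical_prediction_is_tp(self):
        gt = [ScoredBox("i", (10, 10, 20, 20), 1.0)]
        pred = [ScoredBox("i", (10, 10, 20, 20), 0.9)]
        assert pl.match_detections(pred, gt).tolist() == [True]
        assert pl.box_iou(pred[0].bbox, gt[0].bbox) == 1.0

    def test_duplicate_predictions_single_match(self):
        gt = [ScoredBox("i", (10, 10, 20, 20), 1.0)]
        pred = [
            ScoredBox("i", (10, 10, 20, 20), 0.6),
            ScoredBox("i", (11, 11, 20, 20), 0.9),
        ]
        flags = pl.match_detections(pred, gt)
        assert flags.tolist() == [False, True]  # higher score wins

    def test_five_box_scenario_matches_exhaustive_oracle(self):
        gt = [
            ScoredBox("i", (0, 0, 10, 10), 1.0),
            ScoredBox("i", (20, 0, 10, 10), 1.0),
            ScoredBox("i", (40, 0, 10, 10), 1.0),
        ]
        pred = [
            ScoredBox("i", (1, 0, 10, 10), 0.95),   # overlaps gt0
            ScoredBox("i", (0, 1, 10, 10), 0.90),   # overlaps gt0 too
            ScoredBox("i", (21, 1, 10, 10), 0.85),  # overlaps gt1
            ScoredBox("i", (70, 0, 10, 10), 0.80),  # background
            ScoredBox("i", (40, 0, 10, 10), 0.75),  # exact gt2
        ]
        flags = pl.match_detections(pred, gt, iou_threshold=0.5)
        # greedy in score order: p0->gt0 TP, p1 can't reuse gt0 FP,
        # p2->gt1 TP, p3 FP, p4->gt2 TP
        assert flags.tolist() == [True, False, True, False, True]


class TestPRCurveAndAP:
    def test_perfect_detector_ap_one(self):
        gt = _grid_truth(n_images=3, boxes_per=3, seed=5)
        pred = [
            ScoredBox(g.image_ref, g.bbox, 0.9) for g in gt
        ]
        _, _, ap = pl.pr_curve_and_ap(pred, gt)
        assert ap == 1.0

    def test_all_false_positives_ap_zero(self):
        gt = [ScoredBox("i", (0, 0, 10, 10), 1.0)]
        pred = [ScoredBox("i", (200, 200, 10, 10), s) for s in (0.9, 0.5)]
        _, _, ap = pl.pr_curve_and_ap(pred, gt)
        assert ap == 0.0

    def test_six_prediction_worked_example(self):
        """Frozen hand computation of the precision-envelope area.

        3 truths; predictions sorted by score: TP, FP, TP, FP, TP, FP.
        precision = 1, 1/2, 2/3, 2/4, 3/5, 3/6; recall = 1/3, 1/3, 2/3,
        2/3, 1, 1. Envelope at the recall steps: 1, 2/3, 3/5, so
        AP = (1/3)(1) + (1/3)(2/3) + (1/3)(3/5) = 34/45.
        """
        gt = [
            ScoredBox("i", (0, 0, 10, 10), 1.0),
            ScoredBox("i", (20, 0, 10, 10), 1.0),
            ScoredBox("i", (40, 0, 10, 10), 1.0),
        ]
        pred = [
            ScoredBox("i", (0, 0, 10, 10), 0.9),
            ScoredBox("i", (100, 100, 10, 10), 0.8),
            ScoredBox("i", (20, 0, 10, 10), 0.7),
            ScoredBox("i", (21, 1, 10, 10), 0.6),
            ScoredBox("i", (40, 0, 10, 10), 0.5),
            ScoredBox("i", (150, 150, 10, 10), 0.4),
        ]
        precision, recall, ap = pl.pr_curve_and_ap(pred, gt)
        assert ap == pytest.approx(34 / 45, abs=1e-12)
        assert precision.tolist() == [1, 1 / 2, 2 / 3, 2 / 4, 3 / 5, 3 / 6]
        assert recall.tolist() == [1 / 3, 1 / 3, 2 / 3, 2 / 3, 1, 1]

    def test_ap_non_increasing_when_fp_added(self):
        gt = _grid_truth(n_images=2, boxes_per=4, seed=6)
        pred = [ScoredBox(g.image_ref, g.bbox, 0.8) for g in gt[:6]]
        _, _, ap0 = pl.pr_curve_and_ap(pred, gt)
        for fp_score in (0.95, 0.7, 0.1):
            augmented = pred + [ScoredBox(gt[0].image_ref, (400, 400, 20, 20), fp_score)]
            _, _, ap1 = pl.pr_curve_and_ap(augmented, gt)
            assert ap1 <= ap0 + 1e-12


class TestBalancePoint:
    def test_exact_crossing(self):
        p = np.array([0.95, 0.88, 0.70])
        r = np.array([0.50, 0.88, 0.95])
        assert pl.balance_point(p, r) == (0.88, 0.88)

    def test_min_gap_scan_oracle(self):
        rng = np.random.default_rng(8)
        p = np.sort(rng.uniform(0, 1, 20))[::-1]
        r = np.sort(rng.uniform(0, 1, 20))
        got = pl.balance_point(p, r)
        gaps = np.abs(p - r)
        idx = [i for i in range(20) if gaps[i] == gaps.min()]
        best = max(idx, key=lambda i: r[i])
        assert got == (p[best], r[best])

    def test_single_point_curve(self):
        assert pl.balance_point(np.array([0.7]), np.array([0.4])) == (0.7, 0.4)
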