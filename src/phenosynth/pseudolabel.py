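"""Pseudo-label self-training with adaptive confidence thresholds.

A detector trained on synthetic scenes produces scored boxes on real,
unlabeled images. Instead of a fixed confidence cutoff, the threshold is
chosen each round by maximizing the between-class variance of the score
distribution (Otsu's criterion applied to detection confidences): scores
are split at a candidate threshold t into a low and a high group, and

    sigma^2(t) = w0 * w1 * (mu0 - mu1)^2

is maximized over a grid of candidates. The maximizer separates
high-quality from low-quality pseudo-labels most strongly; boxes at or
above it are kept and used to retrain the detector, and the cycle
repeats. The module also provides the greedy IoU matcher and the
precision/recall/AP evaluator used to score label quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Protocol, Sequence, Tuple

import numpy as np

__all__ = [
    "ScoredBox",
    "ThresholdReport",
    "DetectorContract",
    "RoundReport",
    "SelfLearningResult",
    "select_adaptive_threshold",
    "filter_pseudo_labels",
    "self_learning_loop",
    "box_iou",
    "match_detections",
    "pr_curve_and_ap",
    "balance_point",
]


@dataclass
class ScoredBox:
    """A detection or pseudo-label: bbox in COCO (x, y, w, h) pixels."""

    image_ref: str
    bbox: Tuple[float, float, float, float]
    score: float
    category: str = "fruit"
    #: provenance tag used by mock detectors for bookkeeping
    #: ("truth", "false" or "" for real detectors); not serialized.
    origin: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise ValueError(f"bbox must have positive width/height: {self.bbox}")


@dataclass
class ThresholdReport:
    candidate_grid: np.ndarray
    variance_curve: np.ndarray
    chosen: float
    degenerate: bool = False
    #: number of scores >= each candidate, logged for inspection
    high_counts: Optional[np.ndarray] = None


class DetectorContract(Protocol):
    """Minimal interface the self-learning loop needs from a detector.

    ``infer`` must be deterministic given (state, images, seed); ``train``
    returns a new opaque state. Neural detectors plug in here; tests use
    a mock.
    """

    def infer(self, images: Sequence[str], state, seed: int) -> List[ScoredBox]: ...

    def train(self, images: Sequence[str], labels: Sequence[ScoredBox], state): ...


def select_adaptive_threshold(
    scores: Sequence[float], grid_step: float = 0.01
) -> ThresholdReport:
    """Choose the confidence threshold maximizing between-class variance.

    Candidates are ``grid_step, 2*grid_step, ..., < 1``. At each candidate
    t, scores are split into low (< t) and high (>= t) groups with weights
    w0, w1 and means mu0, mu1; the between-class variance
    ``w0*w1*(mu0-mu1)**2`` is computed, and the argmax is returned. Ties
    break toward the lower threshold. If all scores are identical the
    report is flagged degenerate and the grid midpoint is returned.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores to select a threshold")
    if not (0.0 < grid_step < 1.0):
        raise ValueError("grid_step must be in (0, 1)")
    n_steps = int(np.floor((1.0 - 1e-12) / grid_step))
    grid = grid_step * np.arange(1, n_steps + 1)
    grid = grid[grid < 1.0]

    if np.all(scores == scores[0]):
        mid = grid[len(grid) // 2]
        return ThresholdReport(
            candidate_grid=grid,
            variance_curve=np.zeros_like(grid),
            chosen=float(mid),
            degenerate=True,
            high_counts=np.array([(scores >= t).sum() for t in grid]),
        )

    variance = np.empty_like(grid)
    high_counts = np.empty(len(grid), dtype=int)
    n = scores.size
    for i, t in enumerate(grid):
        lo = scores[scores < t]
        hi = scores[scores >= t]
        high_counts[i] = hi.size
        if lo.size == 0 or hi.size == 0:
            variance[i] = 0.0
            continue
        w0 = lo.size / n
        w1 = hi.size / n
        variance[i] = w0 * w1 * (lo.mean() - hi.mean()) ** 2
    best = int(np.argmax(variance))  # first occurrence = lower threshold on ties
    return ThresholdReport(
        candidate_grid=grid,
        variance_curve=variance,
        chosen=float(grid[best]),
        degenerate=False,
        high_counts=high_counts,
    )


def filter_pseudo_labels(
    boxes: Sequence[ScoredBox], threshold: float
) -> List[ScoredBox]:
    """Keep boxes with score >= threshold, preserving order."""
    return [b for b in boxes if b.score >= threshold]


@dataclass
class RoundReport:
    round_index: int
    n_detections: int
    threshold: float
    n_retained: int
    degenerate_threshold: bool
    threshold_report: ThresholdReport = field(repr=False, default=None)


@dataclass
class SelfLearningResult:
    labels: List[ScoredBox]
    rounds: List[RoundReport]
    halted_early: bool = False
    halt_reason: str = ""


def self_learning_loop(
    detector: DetectorContract,
    synthetic_images: Sequence[str],
    synthetic_labels: Sequence[ScoredBox],
    target_images: Sequence[str],
    rounds: int = 3,
    grid_step: float = 0.01,
    seed: int = 0,
) -> SelfLearningResult:
    """Iteratively refine pseudo-labels on unlabeled target images.

    Round 0 trains the detector on the synthetic set. Each round then
    (1) infers on the target images, (2) selects the adaptive threshold
    from the pooled score distribution, (3) filters, and (4) retrains on
    the retained pseudo-labels. The loop halts with a diagnostic if a
    round retains nothing.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    state = detector.train(synthetic_images, synthetic_labels, None)
    reports: List[RoundReport] = []
    labels: List[ScoredBox] = []
    for r in range(rounds):
        detections = detector.infer(target_images, state, seed=seed + r)
        if len(detections) < 2:
            return SelfLearningResult(
                labels, reports, halted_early=True,
                halt_reason=f"round {r}: fewer than 2 detections",
            )
        report = select_adaptive_threshold(
            [b.score for b in detections], grid_step=grid_step
        )
        retained = filter_pseudo_labels(detections, report.chosen)
        reports.append(
            RoundReport(
                round_index=r,
                n_detections=len(detections),
                threshold=report.chosen,
                n_retained=len(retained),
                degenerate_threshold=report.degenerate,
                threshold_report=report,
            )
        )
        if not retained:
            return SelfLearningResult(
                labels, reports, halted_early=True,
                halt_reason=f"round {r}: empty filtered set at t={report.chosen:.3f}",
            )
        labels = retained
        state = detector.train(target_images, retained, state)
    return SelfLearningResult(labels, reports)


# ---------------------------------------------------------------------------
# Evaluation: greedy IoU matching, PR curve, AP, balance point
# ---------------------------------------------------------------------------


def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    """IoU of two (x, y, w, h) boxes (0-based, half-open)."""
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix0 = max(ax0, bx0)
    iy0 = max(ay0, by0)
    ix1 = min(ax0 + aw, bx0 + bw)
    iy1 = min(ay0 + ah, by0 + bh)
    iw = max(0.0, ix1 - ix0)
    ih = max(0.0, iy1 - iy0)
    inter = iw * ih
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    predictions: Sequence[ScoredBox],
    ground_truth: Sequence[ScoredBox],
    iou_threshold: float = 0.5,
) -> np.ndarray:
    """Greedy score-descending matching; returns a boolean TP flag per prediction.

    Predictions are visited in descending score order (ties by input
    order); a prediction is a true positive if it overlaps a same-image,
    not-yet-matched truth box with IoU >= threshold. Each truth box is
    matched at most once.
    """
    order = sorted(
        range(len(predictions)), key=lambda i: (-predictions[i].score, i)
    )
    truth_by_image: dict = {}
    for j, g in enumerate(ground_truth):
        truth_by_image.setdefault(g.image_ref, []).append(j)
    matched = set()
    tp = np.zeros(len(predictions), dtype=bool)
    for i in order:
        p = predictions[i]
        best_iou, best_j = 0.0, -1
        for j in truth_by_image.get(p.image_ref, ()):
            if j in matched:
                continue
            iou = box_iou(p.bbox, ground_truth[j].bbox)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[i] = True
            matched.add(best_j)
    return tp


def pr_curve_and_ap(
    predictions: Sequence[ScoredBox],
    ground_truth: Sequence[ScoredBox],
    iou_threshold: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Precision/recall arrays over the score sweep and all-points AP.

    Predictions are accumulated in descending score order; AP is the area
    under the precision envelope as a function of recall (continuous,
    all-points interpolation).
    """
    if len(ground_truth) == 0:
        raise ValueError("need at least one ground-truth box")
    if len(predictions) == 0:
        return np.array([]), np.array([]), 0.0
    tp = match_detections(predictions, ground_truth, iou_threshold)
    order = sorted(
        range(len(predictions)), key=lambda i: (-predictions[i].score, i)
    )
    tp_sorted = tp[order]
    cum_tp = np.cumsum(tp_sorted)
    cum_fp = np.cumsum(~tp_sorted)
    precision = cum_tp / (cum_tp + cum_fp)
    recall = cum_tp / len(ground_truth)
    # precision envelope: non-increasing from the right
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    ap = float(np.sum((recall - prev_recall) * envelope))
    return precision, recall, ap


def balance_point(
    precision: np.ndarray, recall: np.ndarray
) -> Tuple[float, float]:
    """Curve point minimizing |P - R|; ties break toward higher recall."""
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    if precision.size == 0:
        raise ValueError("empty curve")
    gap = np.abs(precision - recall)
    min_gap = gap.min()
    candidates = np.flatnonzero(gap == min_gap)
    best = candidates[np.argmax(recall[candidates])]
    return float(precision[best]), float(recall[best])
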