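"""Detection evaluation: IoU, greedy matching, per-class AP, and mAP@0.5.

Matching is class-wise and per keyframe cell (video_id, timestamp): in
descending confidence order (ties broken by input order), each detection
claims the unmatched same-class ground-truth box of highest IoU on its
keyframe, and is a true positive iff that IoU reaches the threshold.
Average precision integrates the precision envelope over recall at every
operating point (all-point interpolation); mAP is the unweighted mean over
classes with at least one ground-truth box.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import CLASS_NAMES
from .data_ava import AvaRecord

__all__ = [
    "ResultRecord", "MatchResult", "PrCurve",
    "iou", "match_detections", "precision_recall", "average_precision",
    "mean_ap", "evaluate_detections",
    "read_result_csv", "write_result_csv",
]


@dataclass(frozen=True)
class ResultRecord:
    """One scored detection row (AVA-style result CSV)."""

    video_id: str
    timestamp: int
    box: tuple[float, float, float, float]
    action_id: int
    score: float


@dataclass
class MatchResult:
    """TP/FP flags for one class, ordered by descending confidence."""

    tp_flags: np.ndarray
    fp_flags: np.ndarray
    n_gt: int

    def __post_init__(self):
        assert len(self.tp_flags) == len(self.fp_flags)
        assert self.tp_flags.sum() <= self.n_gt or self.n_gt == 0


@dataclass
class PrCurve:
    recall: np.ndarray     # nondecreasing in [0, 1]
    precision: np.ndarray


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes; degenerate
    (zero-area) boxes score 0 against everything."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    if area_a == 0.0 or area_b == 0.0:
        return 0.0
    ix = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    iy = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = ix * iy
    return inter / (area_a + area_b - inter)


def match_detections(dets: Sequence[ResultRecord], gts: Sequence[AvaRecord],
                     iou_thr: float = 0.5,
                     action_id: int | None = None) -> MatchResult:
    """Greedy confidence-ordered matching for one class.

    When ``action_id`` is given, detections and ground truth are filtered to
    that class first; otherwise all inputs must already share one class.
    Each ground-truth box is claimed at most once.
    """
    if action_id is not None:
        dets = [d for d in dets if d.action_id == action_id]
        gts = [g for g in gts if g.action_id == action_id]
    classes = {d.action_id for d in dets} | {g.action_id for g in gts}
    if len(classes) > 1:
        raise ValueError("matching is per class; filter inputs or pass action_id")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)  # stable
    used: set[tuple] = set()
    gt_by_cell: dict[tuple, list[tuple[int, AvaRecord]]] = {}
    for j, g in enumerate(gts):
        gt_by_cell.setdefault((g.video_id, g.timestamp), []).append((j, g))
    tp = np.zeros(len(order), dtype=bool)
    for rank, i in enumerate(order):
        d = dets[i]
        best_iou, best_j = 0.0, None
        for j, g in gt_by_cell.get((d.video_id, d.timestamp), ()):
            if j in used:
                continue
            v = iou(d.box, g.box)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j is not None and best_iou >= iou_thr:
            tp[rank] = True
            used.add(best_j)
    return MatchResult(tp_flags=tp, fp_flags=~tp, n_gt=len(gts))


def precision_recall(match: MatchResult) -> PrCurve:
    tp_cum = np.cumsum(match.tp_flags)
    fp_cum = np.cumsum(match.fp_flags)
    recall = tp_cum / max(match.n_gt, 1)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    return PrCurve(recall=recall, precision=precision)


def average_precision(match: MatchResult) -> float | None:
    """Area under the precision envelope over recall; None when undefined
    (no ground truth for the class)."""
    if match.n_gt == 0:
        warnings.warn("AP undefined for a class with no ground truth")
        return None
    if len(match.tp_flags) == 0:
        return 0.0
    pr = precision_recall(match)
    mrec = np.concatenate([[0.0], pr.recall, [pr.recall[-1]]])
    mpre = np.concatenate([[1.0], pr.precision, [0.0]])
    # precision envelope (monotone nonincreasing from the right)
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    steps = np.nonzero(np.diff(mrec) > 0)[0]
    return float(np.sum((mrec[steps + 1] - mrec[steps]) * mpre[steps + 1]))


def mean_ap(ap_per_class: dict[int, float | None]) -> float:
    defined = [v for v in ap_per_class.values() if v is not None]
    if not defined:
        raise ValueError("no class has a defined AP")
    return float(np.mean(defined))


def evaluate_detections(dets: Sequence[ResultRecord],
                        gts: Sequence[AvaRecord],
                        iou_thr: float = 0.5) -> dict:
    """Full per-class AP + mAP report for a detection set."""
    classes = sorted({g.action_id for g in gts} | {d.action_id for d in dets})
    ap_per_class: dict[int, float | None] = {}
    for c in classes:
        ap_per_class[c] = average_precision(
            match_detections(dets, gts, iou_thr, action_id=c))
    return {
        "iou_threshold": iou_thr,
        "ap_per_class": {CLASS_NAMES.get(c, str(c)): ap_per_class[c]
                         for c in classes},
        "map": mean_ap(ap_per_class),
    }


# ------------------------------------------------------------------- files
def write_result_csv(records: Iterable[ResultRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for r in records:
            writer.writerow([r.video_id, r.timestamp,
                             *(f"{v:.6f}" for v in r.box),
                             r.action_id, f"{r.score:.6f}"])


def read_result_csv(path) -> list[ResultRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            out.append(ResultRecord(
                video_id=row[0], timestamp=int(row[1]),
                box=tuple(float(v) for v in row[2:6]),
                action_id=int(row[6]), score=float(row[7])))
    return out


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
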