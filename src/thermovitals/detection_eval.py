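"""Bounding-box detection evaluation: IoU, greedy matching, AP/mAP, F1, coverage.

Conventions follow the darknet evaluator: predictions are matched per
class greedily in order of descending confidence at an IoU threshold of
0.5; average precision integrates the monotonized precision-recall curve
with all-point (continuous) interpolation; "average IoU" is computed over
matched true-positive pairs only; classes absent from the ground truth
are excluded from the mAP mean.  Confidence ties are broken by input
order so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .irt_io import CLASS_NAMES, BoundingBox, RoiTrack

__all__ = [
    "MatchResult",
    "DetectionMetrics",
    "iou",
    "match_detections",
    "average_precision",
    "f1_score",
    "detection_coverage",
    "evaluate_tracks",
]

DEFAULT_IOU_THRESHOLD = 0.5


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    matched_ious: list[float] = field(default_factory=list)


@dataclass
class MatchResult:
    """Per-class TP/FP/FN counts plus the IoUs of matched pairs."""

    per_class: dict[str, ClassCounts] = field(default_factory=dict)
    iou_threshold: float = DEFAULT_IOU_THRESHOLD

    def counts(self, label: str) -> ClassCounts:
        return self.per_class.setdefault(label, ClassCounts())

    @property
    def tp(self) -> int:
        return sum(c.tp for c in self.per_class.values())

    @property
    def fp(self) -> int:
        return sum(c.fp for c in self.per_class.values())

    @property
    def fn(self) -> int:
        return sum(c.fn for c in self.per_class.values())

    def merge(self, other: "MatchResult") -> "MatchResult":
        out = MatchResult(iou_threshold=self.iou_threshold)
        for src in (self, other):
            for label, c in src.per_class.items():
                acc = out.counts(label)
                acc.tp += c.tp
                acc.fp += c.fp
                acc.fn += c.fn
                acc.matched_ious.extend(c.matched_ious)
        return out


@dataclass
class DetectionMetrics:
    avg_iou: dict[str, float]
    ap: dict[str, float]
    map: float
    f1: float
    match: MatchResult


def _sorted_by_confidence(preds: Sequence[BoundingBox]) -> list[BoundingBox]:
    # stable sort keeps input order for equal confidences
    return sorted(preds, key=lambda b: -(b.confidence if b.confidence is not None else 1.0))


def match_detections(
    preds: Sequence[BoundingBox],
    truths: Sequence[BoundingBox],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedy confidence-ordered matching within a single frame.

    Each prediction claims the unmatched same-class ground truth of
    highest IoU, provided that IoU reaches the threshold; leftover
    predictions are false positives and leftover truths false negatives.
    """
    result = MatchResult(iou_threshold=iou_threshold)
    for label in {b.label for b in truths} | {b.label for b in preds}:
        cls_truths = [t for t in truths if t.label == label]
        cls_preds = _sorted_by_confidence([p for p in preds if p.label == label])
        counts = result.counts(label)
        claimed = [False] * len(cls_truths)
        for p in cls_preds:
            best_i, best_iou = -1, 0.0
            for i, t in enumerate(cls_truths):
                if claimed[i]:
                    continue
                v = iou(p, t)
                if v > best_iou:
                    best_i, best_iou = i, v
            if best_i >= 0 and best_iou >= iou_threshold:
                claimed[best_i] = True
                counts.tp += 1
                counts.matched_ious.append(best_iou)
            else:
                counts.fp += 1
        counts.fn += claimed.count(False)
    return result


def _ap_from_flags(tp_flags: np.ndarray, n_truths: int) -> float:
    """Area under the monotonized PR curve (all-point interpolation)."""
    if n_truths == 0:
        raise ValueError("AP undefined without ground truth of the class")
    if tp_flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_truths
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope: max precision at any recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def _pooled_tp_flags(
    preds_by_frame: Mapping[int, Sequence[BoundingBox]],
    truths_by_frame: Mapping[int, Sequence[BoundingBox]],
    label: str,
    iou_threshold: float,
) -> tuple[np.ndarray, int]:
    records: list[tuple[float, int, int, BoundingBox]] = []  # (-conf, frame, order, box)
    for frame, boxes in preds_by_frame.items():
        for order, b in enumerate(boxes):
            if b.label == label:
                conf = b.confidence if b.confidence is not None else 1.0
                records.append((-conf, frame, order, b))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    claimed: dict[int, list[bool]] = {}
    truths: dict[int, list[BoundingBox]] = {
        frame: [t for t in boxes if t.label == label] for frame, boxes in truths_by_frame.items()
    }
    n_truths = sum(len(v) for v in truths.values())
    flags = np.zeros(len(records), dtype=bool)
    for k, (_, frame, _, p) in enumerate(records):
        cls_truths = truths.get(frame, [])
        marks = claimed.setdefault(frame, [False] * len(cls_truths))
        best_i, best_iou = -1, 0.0
        for i, t in enumerate(cls_truths):
            if marks[i]:
                continue
            v = iou(p, t)
            if v > best_iou:
                best_i, best_iou = i, v
        if best_i >= 0 and best_iou >= iou_threshold:
            marks[best_i] = True
            flags[k] = True
    return flags, n_truths


def average_precision(
    preds: Sequence[BoundingBox] | Mapping[int, Sequence[BoundingBox]],
    truths: Sequence[BoundingBox] | Mapping[int, Sequence[BoundingBox]],
    label: str,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> float:
    """AP for one class over a frame (lists) or a whole track (mappings).

    Raises ``ValueError`` when the ground truth contains no box of the
    class — such classes are excluded from mAP rather than scored 0.
    """
    if not isinstance(preds, Mapping):
        preds = {0: list(preds)}
    if not isinstance(truths, Mapping):
        truths = {0: list(truths)}
    flags, n_truths = _pooled_tp_flags(preds, truths, label, iou_threshold)
    return _ap_from_flags(flags, n_truths)


def f1_score(match: MatchResult) -> float:
    """Micro-averaged F1 (harmonic mean of precision and recall)."""
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fp == 0 and tp + fn == 0:
        raise ValueError("F1 undefined: no predictions and no ground truth")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def detection_coverage(track: RoiTrack, label: str, n_frames: int) -> float:
    """Percentage of frames with at least one box of ``label``."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    hit = sum(1 for i in range(n_frames) if any(b.label == label for b in track.boxes(i)))
    return 100.0 * hit / n_frames


def evaluate_tracks(
    pred_track: RoiTrack,
    truth_track: RoiTrack,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> DetectionMetrics:
    """Full per-class report over a sequence: avg IoU, AP, mAP, micro F1."""
    frames = sorted(set(pred_track.entries) | set(truth_track.entries))
    match = MatchResult(iou_threshold=iou_threshold)
    for idx in frames:
        match = match.merge(
            match_detections(pred_track.boxes(idx), truth_track.boxes(idx), iou_threshold)
        )
    preds_by_frame = {i: pred_track.boxes(i) for i in frames}
    truths_by_frame = {i: truth_track.boxes(i) for i in frames}
    present = {
        label
        for label in CLASS_NAMES
        if any(b.label == label for boxes in truths_by_frame.values() for b in boxes)
    }
    ap = {
        label: average_precision(preds_by_frame, truths_by_frame, label, iou_threshold)
        for label in sorted(present)
    }
    avg_iou = {
        label: (float(np.mean(c.matched_ious)) if c.matched_ious else float("nan"))
        for label, c in match.per_class.items()
    }
    map_value = float(np.mean(list(ap.values()))) if ap else float("nan")
    return DetectionMetrics(avg_iou=avg_iou, ap=ap, map=map_value, f1=f1_score(match), match=match)
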