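"""Detection evaluation: greedy matching, precision/recall, mAP, metric SD.

Average precision uses all-point interpolation of the precision-recall curve
built from the globally confidence-sorted detection list (COCO-style
convention); confidence ties are broken by detection input order (stable
sort).  ``mAP`` is the mean of per-class APs; classes without ground truth
are excluded from the mean.  ``metric_sd`` is the sample standard deviation
(N-1 denominator) used for repeat-seed stability reports.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .model import Detection, box_iou_matrix
from .phantom import Annotation

COCO_THRESHOLDS = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))
SMALL_AREA = 32.0 * 32.0


@dataclasses.dataclass
class MatchResult:
    """Per-detection TP/FP flags at one IoU threshold, plus FN count."""

    tp: np.ndarray          # bool, ordered like the (sorted) detections
    scores: np.ndarray
    classes: np.ndarray
    n_gt: int

    @property
    def fn(self) -> int:
        return self.n_gt - int(self.tp.sum())


@dataclasses.dataclass
class EvalSummary:
    precision: float
    recall: float
    per_class_ap: dict[int, float]
    map50: float
    map50_95: float
    ap_small: Optional[float] = None

    def report(self) -> str:
        lines = ["metric          value",
                 f"precision       {self.precision:.4f}",
                 f"recall          {self.recall:.4f}",
                 f"mAP_0.5         {self.map50:.4f}",
                 f"mAP_0.5:0.95    {self.map50_95:.4f}"]
        if self.ap_small is not None:
            lines.append(f"AP_small        {self.ap_small:.4f}")
        for c, ap in sorted(self.per_class_ap.items()):
            lines.append(f"AP[class {c}]    {ap:.4f}")
        return "\n".join(lines)


def match_detections(detections: Sequence[Detection],
                     ground_truths: Sequence[Annotation],
                     iou_threshold: float) -> MatchResult:
    """Greedy confidence-ordered matching; each GT matched at most once."""
    order = sorted(range(len(detections)),
                   key=lambda i: -detections[i].score)
    tp = np.zeros(len(detections), dtype=bool)
    scores = np.array([detections[i].score for i in order], dtype=np.float32)
    classes = np.array([detections[i].class_id for i in order], dtype=np.int64)
    if ground_truths:
        gt_boxes = np.array([g.box for g in ground_truths], dtype=np.float32)
        gt_cls = np.array([g.class_id for g in ground_truths])
        taken = np.zeros(len(ground_truths), dtype=bool)
        for rank, i in enumerate(order):
            det = detections[i]
            box = np.array([det.box], dtype=np.float32)
            ious = box_iou_matrix(box, gt_boxes)[0]
            ious[taken | (gt_cls != det.class_id)] = -1.0
            j = int(np.argmax(ious))
            if ious[j] >= iou_threshold:
                taken[j] = True
                tp[rank] = True
    return MatchResult(tp, scores, classes, len(ground_truths))


def _average_precision(tp: np.ndarray, scores: np.ndarray, n_gt: int) -> float:
    """All-point interpolated AP from global confidence-sorted flags."""
    if n_gt == 0:
        return math.nan
    if len(tp) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope (monotone non-increasing from the right)
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.flatnonzero(mrec[1:] != mrec[:-1])
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_average_precision(per_image: Sequence[tuple[Sequence[Detection],
                                                     Sequence[Annotation]]],
                           thresholds: Sequence[float] = COCO_THRESHOLDS
                           ) -> EvalSummary:
    """Dataset-level evaluation from per-image (detections, ground truths)."""
    n_gt_total = sum(len(g) for _, g in per_image)
    if n_gt_total == 0:
        raise ValueError("evaluation needs at least one ground-truth object")
    classes = sorted({g.class_id for _, gts in per_image for g in gts})

    def ap_at(thr: float) -> dict[int, float]:
        per_class: dict[int, float] = {}
        for c in classes:
            tps, scs = [], []
            n_gt = 0
            for dets, gts in per_image:
                dc = [d for d in dets if d.class_id == c]
                gc = [g for g in gts if g.class_id == c]
                m = match_detections(dc, gc, thr)
                tps.append(m.tp)
                scs.append(m.scores)
                n_gt += m.n_gt
            if n_gt == 0:
                continue
            per_class[c] = _average_precision(
                np.concatenate(tps) if tps else np.zeros(0, bool),
                np.concatenate(scs) if scs else np.zeros(0), n_gt)
        return per_class

    ap50 = ap_at(0.5)
    map50 = float(np.mean(list(ap50.values())))
    maps = [map50 if abs(t - 0.5) < 1e-9
            else float(np.mean(list(ap_at(t).values()))) for t in thresholds]
    map50_95 = float(np.mean(maps))

    # dataset precision/recall at the detections' own confidence cut
    tp = fp = fn = 0
    for dets, gts in per_image:
        m = match_detections(dets, gts, 0.5)
        tp += int(m.tp.sum())
        fp += int((~m.tp).sum())
        fn += m.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0

    # COCO-style small objects: restrict ground truth to area < 32^2 and
    # ignore detections that overlap larger objects
    small_pairs = []
    any_small = False
    for dets, gts in per_image:
        small = [g for g in gts if _area(g) < SMALL_AREA]
        large = [g for g in gts if _area(g) >= SMALL_AREA]
        keep = []
        for d in dets:
            if large:
                ious = box_iou_matrix(np.array([d.box], np.float32),
                                      np.array([g.box for g in large], np.float32))[0]
                if ious.max() >= 0.5:
                    continue
            keep.append(d)
        small_pairs.append((keep, small))
        any_small = any_small or bool(small)
    ap_small = None
    if any_small:
        per_class_small = []
        for c in classes:
            tps, scs = [], []
            n_gt = 0
            for dets, gts in small_pairs:
                m = match_detections([d for d in dets if d.class_id == c],
                                     [g for g in gts if g.class_id == c], 0.5)
                tps.append(m.tp)
                scs.append(m.scores)
                n_gt += m.n_gt
            if n_gt:
                per_class_small.append(_average_precision(
                    np.concatenate(tps), np.concatenate(scs), n_gt))
        ap_small = float(np.mean(per_class_small))
    return EvalSummary(precision, recall, ap50, map50, map50_95, ap_small)


def _area(g: Annotation) -> float:
    x1, y1, x2, y2 = g.box
    return (x2 - x1) * (y2 - y1)


def metric_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (N-1 denominator) of repeated readings."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("metric_sd needs at least 2 readings")
    return float(v.std(ddof=1))


def dataset_recall(per_image, iou_threshold: float = 0.5) -> float:
    """TP / (TP + FN) over a dataset at one IoU threshold."""
    tp = fn = 0
    for dets, gts in per_image:
        m = match_detections(dets, gts, iou_threshold)
        tp += int(m.tp.sum())
        fn += m.fn
    return tp / (tp + fn) if tp + fn else 0.0
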