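"""Detection evaluation: greedy IoU matching, AP/mAP at IoU 0.5, confusion
metrics with explicit background accounting, and bootstrap resampling.

Detection has no native true negatives; following the documented convention
here, each image contributes `n_neg` seeded background candidate boxes
(IoU < 0.1 with every ground truth). A candidate is a TN when no retained
prediction overlaps it at IoU >= 0.5; overlapped candidates are ignored
because the offending prediction is already an FP through matching.
Absolute specificity/accuracy therefore depend on `n_neg`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateBoxError

__all__ = ["MatchCounts", "MetricsReport", "EvalRecord", "iou",
           "match_detections", "evaluate_images", "average_precision",
           "map_at_50", "confusion_metrics", "bootstrap_metrics"]


def iou(box_a, box_b) -> float:
    """Intersection over union of two half-open corner boxes."""
    a = np.asarray(box_a, dtype=float)
    b = np.asarray(box_b, dtype=float)
    if a[2] <= a[0] or a[3] <= a[1] or b[2] <= b[0] or b[3] <= b[1]:
        raise DegenerateBoxError("boxes must have positive width and height")
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    per_class: dict = field(default_factory=dict)  # class_id -> (tp, fp, fn)

    def __add__(self, other):
        per = {k: tuple(np.add(self.per_class.get(k, (0, 0, 0)),
                               other.per_class.get(k, (0, 0, 0))))
               for k in set(self.per_class) | set(other.per_class)}
        return MatchCounts(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn, self.tn + other.tn, per)


@dataclass
class MetricsReport:
    recall: float
    precision: float
    specificity: float
    accuracy: float
    per_class_ap: dict
    map50: float
    n_boot: int = 0
    bootstrap: dict = field(default_factory=dict)  # metric -> summary stats


def _match_single(boxes, scores, gt_boxes, iou_threshold):
    """Greedy one-to-one matching for one image and one class.

    Returns (order, flags): prediction indices in ranked order and a boolean
    TP flag per ranked prediction. Ties in score prefer larger best-IoU,
    then input order.
    """
    m = len(scores)
    best_iou = np.zeros(m)
    ious = np.zeros((m, len(gt_boxes)))
    for i in range(m):
        for j, g in enumerate(gt_boxes):
            ious[i, j] = iou(boxes[i], g)
        if len(gt_boxes):
            best_iou[i] = ious[i].max()
    order = sorted(range(m), key=lambda i: (-scores[i], -best_iou[i], i))
    taken = np.zeros(len(gt_boxes), dtype=bool)
    flags = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if len(gt_boxes) == 0:
            continue
        cand = np.where(~taken)[0]
        if cand.size == 0:
            continue
        j = cand[np.argmax(ious[i, cand])]
        if ious[i, j] >= iou_threshold:
            taken[j] = True
            flags[rank] = True
    return order, flags


@dataclass
class EvalRecord:
    """Per-image evaluation state, sufficient for bootstrap resampling."""

    image_id: int
    counts: MatchCounts                       # at the score threshold
    ap_flags: dict                            # class -> (scores, tp_flags) full list
    n_gt: dict                                # class -> ground-truth count


def _sample_negatives(gt_boxes, height, width, n_neg, rng):
    """Background candidate boxes with IoU < 0.1 against every ground truth."""
    out = []
    for _ in range(n_neg * 20):
        if len(out) >= n_neg:
            break
        w = rng.uniform(0.05, 0.25) * width
        h = rng.uniform(0.05, 0.25) * height
        x = rng.uniform(0, width - w)
        y = rng.uniform(0, height - h)
        box = np.array([x, y, x + w, y + h])
        if all(iou(box, g) < 0.1 for g in gt_boxes):
            out.append(box)
    return out


def evaluate_images(predictions, ground_truth, iou_threshold: float = 0.5,
                    score_threshold: float = 0.3, n_neg: int = 20,
                    seed: int = 0) -> list:
    """Match predictions to ground truth image by image.

    `predictions` is a list of :class:`~ctcforge.data.Prediction` aligned
    with the samples of `ground_truth` (a DetectionDataset or list of
    ImageSample). Returns one :class:`EvalRecord` per image.
    """
    samples = list(ground_truth)
    if len(predictions) != len(samples):
        raise ValueError("one Prediction per ground-truth image is required")
    records = []
    for pred, sample in zip(predictions, samples):
        classes = sorted({a.class_id for a in sample.annotations}
                         | {int(c) for c in np.asarray(pred.class_ids).tolist()})
        counts = MatchCounts()
        ap_flags, n_gt = {}, {}
        retained_boxes = []
        for c in classes:
            gt_boxes = [a.bbox for a in sample.annotations if a.class_id == c]
            sel = np.asarray(pred.class_ids) == c
            boxes = np.asarray(pred.boxes, dtype=float).reshape(-1, 4)[sel]
            scores = np.asarray(pred.scores, dtype=float)[sel]
            # full ranked list for AP
            order, flags = _match_single(boxes, scores, gt_boxes, iou_threshold)
            ap_flags[c] = (scores[order], flags)
            n_gt[c] = len(gt_boxes)
            # thresholded subset for the confusion counts
            keep = scores >= score_threshold
            rboxes, rscores = boxes[keep], scores[keep]
            retained_boxes.extend(list(rboxes))
            _, rflags = _match_single(rboxes, rscores, gt_boxes, iou_threshold)
            tp = int(rflags.sum())
            fp = int(len(rscores) - tp)
            fn = int(len(gt_boxes) - tp)
            counts.per_class[c] = (tp, fp, fn)
            counts.tp += tp
            counts.fp += fp
            counts.fn += fn
        rng = np.random.default_rng(np.random.SeedSequence([seed, sample.image_id]))
        negs = _sample_negatives([a.bbox for a in sample.annotations],
                                 sample.height, sample.width, n_neg, rng)
        for nb in negs:
            overlapped = any(iou(nb, rb) >= iou_threshold for rb in retained_boxes
                             if rb[2] > rb[0] and rb[3] > rb[1])
            if not overlapped:
                counts.tn += 1
        records.append(EvalRecord(image_id=sample.image_id, counts=counts,
                                  ap_flags=ap_flags, n_gt=n_gt))
    return records


def match_detections(predictions, ground_truth, iou_threshold: float = 0.5,
                     score_threshold: float = 0.3, n_neg: int = 20,
                     seed: int = 0):
    """Pooled match counts plus per-prediction TP/FP flags per class."""
    records = evaluate_images(predictions, ground_truth, iou_threshold,
                              score_threshold, n_neg, seed)
    total = MatchCounts()
    for r in records:
        total = total + r.counts
    flags = _pool_flags(records)
    return total, flags


def _pool_flags(records):
    """Concatenate per-image ranked lists into per-class (scores, flags)."""
    pooled = {}
    for r in records:
        for c, (scores, flags) in r.ap_flags.items():
            s, f = pooled.setdefault(c, ([], []))
            s.extend(scores.tolist())
            f.extend(flags.tolist())
    return {c: (np.asarray(s), np.asarray(f, dtype=bool))
            for c, (s, f) in pooled.items()}


def average_precision(scores, tp_flags, n_ground_truth: int) -> float:
    """All-point interpolated AP from a ranked TP/FP list.

    Precision is replaced by its monotone (right-to-left) envelope and
    integrated over recall.
    """
    if n_ground_truth == 0:
        return float("nan")
    scores = np.asarray(scores, dtype=float)
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if scores.size == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    flags = tp_flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_ground_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone envelope
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, prec_env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def map_at_50(records) -> tuple:
    """(mAP, per-class AP) over classes present in the ground truth."""
    pooled = _pool_flags(records)
    n_gt = {}
    for r in records:
        for c, n in r.n_gt.items():
            n_gt[c] = n_gt.get(c, 0) + n
    aps = {}
    for c, total in n_gt.items():
        if total == 0:
            continue
        scores, flags = pooled.get(c, (np.array([]), np.array([], dtype=bool)))
        aps[c] = average_precision(scores, flags, total)
    mAP = float(np.mean(list(aps.values()))) if aps else float("nan")
    return mAP, aps


def confusion_metrics(counts: MatchCounts) -> dict:
    """Recall, precision, specificity, accuracy; NaN marks 0/0 cases."""
    def ratio(num, den):
        return float(num) / den if den > 0 else float("nan")

    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    return {
        "recall": ratio(tp, tp + fn),
        "precision": ratio(tp, tp + fp),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
    }


def _point_report(records) -> dict:
    total = MatchCounts()
    for r in records:
        total = total + r.counts
    metrics = confusion_metrics(total)
    mAP, aps = map_at_50(records)
    metrics["map50"] = mAP
    return metrics, aps


def bootstrap_metrics(records, n_boot: int = 1000, seed: int = 0,
                      with_map: bool = True) -> MetricsReport:
    """Resample images with replacement and summarize metric distributions."""
    if not records:
        raise ValueError("need at least one evaluated image")
    point, aps = _point_report(records)
    rng = np.random.default_rng(seed)
    n = len(records)
    names = ["recall", "precision", "specificity", "accuracy"] + (
        ["map50"] if with_map else [])
    dists = {k: np.empty(n_boot) for k in names}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = [records[i] for i in idx]
        m, _ = _point_report(sub) if with_map else (None, None)
        if not with_map:
            total = MatchCounts()
            for r in sub:
                total = total + r.counts
            m = confusion_metrics(total)
        for k in names:
            dists[k][b] = m[k]
    summaries = {}
    with warnings.catch_warnings():
        # resamples with no positives yield NaN metrics; summaries ignore them
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, v in dists.items():
            summaries[k] = {
                "mean": float(np.nanmean(v)),
                "sd": float(np.nanstd(v, ddof=1)) if n_boot > 1 else 0.0,
                "q1": float(np.nanpercentile(v, 25)),
                "median": float(np.nanpercentile(v, 50)),
                "q3": float(np.nanpercentile(v, 75)),
            }
    return MetricsReport(recall=point["recall"], precision=point["precision"],
                         specificity=point["specificity"], accuracy=point["accuracy"],
                         per_class_ap=aps, map50=point["map50"],
                         n_boot=n_boot, bootstrap=summaries)
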