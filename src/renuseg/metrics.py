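"""Detection and segmentation evaluation for instance labellings.

Detection follows an overlap-ratio criterion: a reference nucleus is
detected when the best-overlapping segmented object reaches a Jaccard
(IoU) threshold, 0.5 by default.  Segmentation quality is summarised by
per-object Dice/Jaccard over the matched pairs, the Aggregated Jaccard
Index (AJI), and a detection suite (precision/recall/F1 and mean average
precision over the 0.50..0.95 IoU grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchResult",
    "MetricsReport",
    "jaccard",
    "object_dice",
    "match_detections",
    "sensitivity",
    "sensitivity_from_counts",
    "aggregate_segmentation",
    "aji",
    "detection_suite",
    "IOU_GRID",
]

IOU_GRID = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))  # 0.50 .. 0.95


# ---------------------------------------------------------------------------
# pairwise set measures
# ---------------------------------------------------------------------------


def jaccard(obj: np.ndarray, ref: np.ndarray) -> float:
    """Intersection over union of two pixel sets (boolean masks)."""
    obj = np.asarray(obj, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if obj.shape != ref.shape:
        raise ValueError("masks must share a shape")
    union = np.logical_or(obj, ref).sum()
    if union == 0:
        raise ValueError("Jaccard undefined for two empty sets")
    return float(np.logical_and(obj, ref).sum() / union)


def object_dice(obj: np.ndarray, ref: np.ndarray) -> float:
    """Dice coefficient ``2|A∩B| / (|A|+|B|)`` of two pixel sets."""
    obj = np.asarray(obj, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if obj.shape != ref.shape:
        raise ValueError("masks must share a shape")
    total = int(obj.sum()) + int(ref.sum())
    if total == 0:
        raise ValueError("Dice undefined for two empty sets")
    return float(2.0 * np.logical_and(obj, ref).sum() / total)


# ---------------------------------------------------------------------------
# instance matching
# ---------------------------------------------------------------------------


def _contingency(pred: np.ndarray, gt: np.ndarray):
    """Sparse intersection counts between instance labellings.

    Returns (areas_pred, areas_gt, dict[(g, p)] -> intersection).
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("labelings must share a shape")
    areas_p = np.bincount(pred.ravel())
    areas_g = np.bincount(gt.ravel())
    both = (pred > 0) & (gt > 0)
    npred = pred.max(initial=0)
    codes = gt[both].astype(np.int64) * (npred + 1) + pred[both]
    uniq, counts = np.unique(codes, return_counts=True)
    inter = {(int(c // (npred + 1)), int(c % (npred + 1))): int(n)
             for c, n in zip(uniq, counts)}
    return areas_p, areas_g, inter


@dataclass
class MatchResult:
    """Per-reference best match at a given IoU threshold."""

    threshold: float
    matches: dict  # ref id -> (object id, iou)
    detected: dict  # ref id -> bool
    unmatched_objects: list
    n_references: int
    n_objects: int

    @property
    def n_detected(self) -> int:
        return int(sum(self.detected.values()))


def match_detections(pred_labels: np.ndarray, gt_labels: np.ndarray,
                     T: float = 0.5, strict: bool = False) -> MatchResult:
    """Match each reference nucleus to its best-overlapping object.

    A reference is detected when the largest overlap ratio reaches ``T``
    (``>= T``, or ``> T`` when ``strict``).  Ties on the overlap ratio are
    broken toward the smaller object id for determinism.
    """
    areas_p, areas_g, inter = _contingency(pred_labels, gt_labels)
    n_refs = len(areas_g) - 1
    n_objs = len(areas_p) - 1

    best: dict[int, tuple[int, float]] = {}
    for (g, p), i in sorted(inter.items()):
        iou = i / (areas_g[g] + areas_p[p] - i)
        if g not in best or iou > best[g][1] + 1e-15:
            best[g] = (p, iou)
    matches = dict(best)
    detected = {
        g: (matches[g][1] > T if strict else matches[g][1] >= T)
        if g in matches else False
        for g in range(1, n_refs + 1)
    }
    matched_objs = {matches[g][0] for g in matches if detected[g]}
    unmatched = [p for p in range(1, n_objs + 1) if p not in matched_objs]
    return MatchResult(
        threshold=T,
        matches=matches,
        detected=detected,
        unmatched_objects=unmatched,
        n_references=n_refs,
        n_objects=n_objs,
    )


def sensitivity(match: MatchResult) -> float:
    """Detected references over total references."""
    if match.n_references == 0:
        raise ValueError("sensitivity undefined without reference nuclei")
    return match.n_detected / match.n_references


def sensitivity_from_counts(detected: int, total: int) -> float:
    if total <= 0:
        raise ValueError("sensitivity undefined without reference nuclei")
    return detected / total


def aggregate_segmentation(match: MatchResult, pred_labels: np.ndarray,
                           gt_labels: np.ndarray, min_iou: float = 0.5):
    """Mean +/- sd of per-object Dice and Jaccard over pairs with IoU >= 0.5.

    Returns a dict or ``None`` when no pair qualifies.
    """
    areas_p, areas_g, inter = _contingency(pred_labels, gt_labels)
    dices, jacs = [], []
    for g, (p, iou) in match.matches.items():
        if iou < min_iou:
            continue
        i = inter[(g, p)]
        dices.append(2.0 * i / (areas_g[g] + areas_p[p]))
        jacs.append(iou)
    if not dices:
        return None
    return {
        "dice_mean": float(np.mean(dices)),
        "dice_sd": float(np.std(dices)),
        "jaccard_mean": float(np.mean(jacs)),
        "jaccard_sd": float(np.std(jacs)),
        "n_pairs": len(dices),
    }


# ---------------------------------------------------------------------------
# aggregated Jaccard index
# ---------------------------------------------------------------------------


def aji(pred_labels: np.ndarray, gt_labels: np.ndarray) -> float:
    """Aggregated Jaccard Index.

    For each ground-truth instance, in label order, greedily assign the
    still-unused prediction with the largest IoU; sum the pairwise
    intersections over the pairwise unions, and add the areas of predictions
    that were never assigned to the denominator.  Unmatched ground truths
    contribute their own area to the denominator.
    """
    areas_p, areas_g, inter = _contingency(pred_labels, gt_labels)
    n_refs = len(areas_g) - 1
    if n_refs == 0:
        raise ValueError("AJI undefined for empty ground truth")
    used: set[int] = set()
    num = 0.0
    den = 0.0
    for g in range(1, n_refs + 1):
        best_p, best_iou = 0, -1.0
        for (gg, p), i in inter.items():
            if gg != g or p in used:
                continue
            iou = i / (areas_g[g] + areas_p[p] - i)
            if iou > best_iou + 1e-15 or (abs(iou - best_iou) <= 1e-15 and p < best_p):
                best_p, best_iou = p, iou
        if best_p:
            i = inter[(g, best_p)]
            num += i
            den += areas_g[g] + areas_p[best_p] - i
            used.add(best_p)
        else:
            den += areas_g[g]
    for p in range(1, len(areas_p)):
        if p not in used and areas_p[p] > 0:
            den += areas_p[p]
    return float(num / den) if den else 0.0


# ---------------------------------------------------------------------------
# detection suite
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    sensitivity: float | None = None
    segmentation: dict | None = None
    aji: float | None = None
    map_score: float | None = None
    per_threshold: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "segmentation": self.segmentation,
            "aji": self.aji,
            "mAP": self.map_score,
            "per_threshold": self.per_threshold,
        }


def detection_suite(pred_labels: np.ndarray, gt_labels: np.ndarray,
                    iou_grid=IOU_GRID) -> MetricsReport:
    """Precision/recall/F1 at each IoU threshold plus their mean precision.

    With no confidence ranking available for a thresholded likelihood map,
    the mean average precision is the mean of the precision values over the
    IoU grid.
    """
    report = MetricsReport(per_threshold={})
    precisions = []
    for tau in iou_grid:
        m = match_detections(pred_labels, gt_labels, T=float(tau))
        matched_objs = {m.matches[g][0] for g in m.matches if m.detected[g]}
        precision = len(matched_objs) / m.n_objects if m.n_objects else 0.0
        recall = m.n_detected / m.n_references if m.n_references else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        report.per_threshold[float(tau)] = {
            "precision": precision, "recall": recall, "f1": f1,
        }
        precisions.append(precision)
    report.map_score = float(np.mean(precisions)) if precisions else None
    return report
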