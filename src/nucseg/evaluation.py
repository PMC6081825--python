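"""Object-level evaluation: IoU-matched precision/recall/F1 and the
touching-nuclei separation assay.

An instance pair counts as a true positive only when its IoU is
*strictly* greater than the threshold (default 0.5).  Matching is
one-to-one, greedy in descending IoU; at thresholds >= 0.5 a predicted
object can exceed the threshold with at most one ground-truth object,
so greedy matching is equivalent to the optimal assignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MatchResult:
    true_positive: int
    false_positive: int
    false_negative: int
    pairs: tuple  # of (gt_label, pred_label, iou)


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    standard_error: float = 0.0
    n_pixels: int = 0


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """|A n B| / |A u B| of two boolean pixel sets on the same grid."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("pixel sets must share a grid")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU of two empty sets is undefined")
    return float(np.logical_and(a, b).sum() / union)


def _iou_table(gt: np.ndarray, pred: np.ndarray):
    """Sparse IoU table between all gt/pred label pairs via joint counts."""
    gt = np.asarray(gt).ravel()
    pred = np.asarray(pred).ravel()
    n_gt, n_pred = int(gt.max(initial=0)), int(pred.max(initial=0))
    gt_areas = np.bincount(gt, minlength=n_gt + 1)
    pred_areas = np.bincount(pred, minlength=n_pred + 1)
    # objects present = labels with nonzero area (labels need not be
    # consecutive)
    count_gt = int((gt_areas[1:] > 0).sum())
    count_pred = int((pred_areas[1:] > 0).sum())
    both = (gt > 0) & (pred > 0)
    joint = gt[both].astype(np.int64) * (n_pred + 1) + pred[both]
    inter = np.bincount(joint, minlength=(n_gt + 1) * (n_pred + 1))
    entries = []
    for key in np.nonzero(inter)[0]:
        g, p = divmod(int(key), n_pred + 1)
        i = inter[key]
        entries.append((g, p, i / (gt_areas[g] + pred_areas[p] - i)))
    return entries, count_gt, count_pred


def match_objects(gt: np.ndarray, pred: np.ndarray,
                  iou_threshold: float = 0.5) -> MatchResult:
    """One-to-one greedy matching by descending IoU; strict threshold."""
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("masks must share a grid")
    entries, n_gt, n_pred = _iou_table(gt, pred)
    # IoU descending; label order breaks exact ties deterministically
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    used_gt, used_pred, pairs = set(), set(), []
    for g, p, val in entries:
        if val <= iou_threshold:
            break
        if g in used_gt or p in used_pred:
            continue
        used_gt.add(g)
        used_pred.add(p)
        pairs.append((g, p, val))
    tp = len(pairs)
    return MatchResult(true_positive=tp,
                       false_positive=n_pred - tp,
                       false_negative=n_gt - tp,
                       pairs=tuple(pairs))


def compute_metrics(match: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and F1 with zero-denominator conventions."""
    tp, fp, fn = match.true_positive, match.false_positive, match.false_negative
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) \
        if precision + recall else 0.0
    return precision, recall, f1


def standard_error(output: np.ndarray, gt: np.ndarray) -> float:
    """sigma / sqrt(n): population SD of per-pixel (output - gt) over the
    total pixel count."""
    output = np.asarray(output, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if output.shape != gt.shape:
        raise ValueError("grids must match")
    if output.size == 0:
        raise ValueError("empty grid")
    diff = output - gt
    return float(diff.std() / np.sqrt(diff.size))


def report(match: MatchResult, output: np.ndarray | None = None,
           gt_map: np.ndarray | None = None) -> MetricsReport:
    precision, recall, f1 = compute_metrics(match)
    se, n_pix = 0.0, 0
    if output is not None and gt_map is not None:
        se = standard_error(output, gt_map)
        n_pix = int(np.asarray(output).size)
    return MetricsReport(precision=precision, recall=recall, f1=f1,
                         standard_error=se, n_pixels=n_pix)


def touching_separation(scene, pred: np.ndarray
                        ) -> tuple[int, int, float]:
    """Count ground-truth touching pairs whose members match two distinct
    predicted labels."""
    match = match_objects(scene.mask, pred)
    assigned = {g: p for g, p, _ in match.pairs}
    total = len(scene.touching_pairs)
    separated = 0
    for a, b in scene.touching_pairs:
        pa, pb = assigned.get(a), assigned.get(b)
        if pa is not None and pb is not None and pa != pb:
            separated += 1
    rate = separated / total if total else 0.0
    return separated, total, rate


def write_report_csv(path, reports: dict[str, MetricsReport]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "precision", "recall", "f1",
                         "standard_error", "n_pixels"])
        for name, r in reports.items():
            writer.writerow([name, f"{r.precision:.6f}", f"{r.recall:.6f}",
                             f"{r.f1:.6f}", f"{r.standard_error:.6e}",
                             r.n_pixels])


def write_match_csv(path, match: MatchResult,
                    gt: np.ndarray | None = None,
                    pred: np.ndarray | None = None) -> None:
    """Per-object match table; unmatched objects are listed as FN/FP when
    the masks are supplied."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gt_label", "pred_label", "iou", "status"])
        for g, p, v in match.pairs:
            writer.writerow([g, p, f"{v:.6f}", "TP"])
        matched_gt = {g for g, _, _ in match.pairs}
        matched_pred = {p for _, p, _ in match.pairs}
        if gt is not None:
            for g in np.unique(gt):
                if g > 0 and g not in matched_gt:
                    writer.writerow([int(g), "", "", "FN"])
        if pred is not None:
            for p in np.unique(pred):
                if p > 0 and p not in matched_pred:
                    writer.writerow(["", int(p), "", "FP"])
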