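"""Detection and classification metrics.

A detection matches a ground-truth box when their intersection covers at
least half of the ground-truth area (the ≥50%-overlap rule); the false
negative rate (FNR) is the fraction of true phytoplankton boxes left
unmatched. Oversegmentation counts specimens covered by two or more
detections; undersegmentation counts detections enclosing two or more
specimens. Classifier quality is summarised by precision–recall curves and
by precision at a fixed recall target, the model-selection fitness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import BoundingBox, GroundTruthBox


@dataclass
class MatchResult:
    """Symmetric detection ↔ ground-truth association under the 50% rule."""

    gt_to_dets: list[list[int]]
    det_to_gts: list[list[int]]


@dataclass
class EvaluationReport:
    fnr: float
    oversegmentation_rate: float
    undersegmentation_rate: float
    pr_curve: np.ndarray | None = None
    precision_at: dict[float, float] = field(default_factory=dict)


def match_detections(dets: list[BoundingBox],
                     gts: list[GroundTruthBox]) -> MatchResult:
    """Match each detection to every GT box it overlaps by ≥50% of GT area.

    The ≥ comparison is inclusive: covering exactly half of the true box
    counts as a match.
    """
    gt_to_dets: list[list[int]] = [[] for _ in gts]
    det_to_gts: list[list[int]] = [[] for _ in dets]
    for gi, gt in enumerate(gts):
        for di, det in enumerate(dets):
            if det.intersection_area(gt.box) >= 0.5 * gt.box.area:
                gt_to_dets[gi].append(di)
                det_to_gts[di].append(gi)
    return MatchResult(gt_to_dets, det_to_gts)


def detection_metrics(
    dets: list[BoundingBox],
    gts: list[GroundTruthBox],
    overseg_coverage: str = "detection",
    underseg_denominator: str = "detections",
) -> EvaluationReport:
    """FNR and over/under-segmentation rates for one detection set.

    FNR is the fraction of phytoplankton GT boxes with no matching detection
    (≥50%-of-GT rule); non-phytoplankton ground truth does not enter the FNR
    because the candidate stage is meant to detect every object.

    Oversegmentation: fraction of GT boxes covered by ≥2 detections. With
    ``overseg_coverage="detection"`` (default) a detection covers a GT box
    when ≥50% of the *detection's* area lies inside it — the reading under
    which several small fragments of one split specimen count; with ``"gt"``
    the ≥50%-of-GT matching is reused (two disjoint detections can then never
    both cover one specimen, so the rate degenerates to ~0).

    Undersegmentation: fraction of detections matching ≥2 GT boxes
    (≥50%-of-GT rule); ``underseg_denominator="gt"`` divides by the GT count
    instead of the detection count.
    """
    if not gts:
        warnings.warn("no ground-truth boxes: rates defined as 0")
        return EvaluationReport(0.0, 0.0, 0.0)
    match = match_detections(dets, gts)
    phyto = [i for i, g in enumerate(gts) if g.label == "phytoplankton"]
    if phyto:
        unmatched = sum(1 for i in phyto if not match.gt_to_dets[i])
        fnr = unmatched / len(phyto)
    else:
        fnr = 0.0

    if overseg_coverage == "detection":
        covered_counts = np.zeros(len(gts), dtype=int)
        for det in dets:
            for gi, gt in enumerate(gts):
                if det.intersection_area(gt.box) >= 0.5 * det.area:
                    covered_counts[gi] += 1
        overseg = float(np.mean(covered_counts >= 2)) if len(gts) else 0.0
    elif overseg_coverage == "gt":
        overseg = float(np.mean([len(m) >= 2 for m in match.gt_to_dets]))
    else:
        raise ValueError(f"unknown overseg_coverage {overseg_coverage!r}")

    n_under = sum(1 for m in match.det_to_gts if len(m) >= 2)
    if underseg_denominator == "detections":
        underseg = n_under / len(dets) if dets else 0.0
    elif underseg_denominator == "gt":
        underseg = n_under / len(gts)
    else:
        raise ValueError(f"unknown underseg_denominator {underseg_denominator!r}")
    return EvaluationReport(fnr, overseg, underseg)


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Precision/recall at every distinct score threshold.

    A sample is predicted positive when ``score >= threshold``. Returns an
    array of (threshold, precision, recall) rows ordered by descending
    threshold, i.e. non-decreasing recall.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("both classes must be present")
    thresholds = np.unique(scores)[::-1]
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        rows.append((t, precision, recall))
    return np.array(rows)


def precision_at_recall(scores: np.ndarray, labels: np.ndarray,
                        target_recall: float) -> float:
    """Best precision achievable at recall ≥ ``target_recall``."""
    curve = pr_curve(scores, labels)
    feasible = curve[curve[:, 2] >= target_recall]
    if len(feasible) == 0:  # unreachable: recall hits 1 at the lowest threshold
        return 0.0
    return float(feasible[:, 1].max())
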