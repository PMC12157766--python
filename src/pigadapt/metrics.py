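"""Detection evaluation: greedy matching and 11-point interpolated AP.

The metric follows the PASCAL-VOC-2007 convention: predictions are sorted
by descending confidence and greedily matched one-to-one to ground truth
at an IoU threshold (default 0.5); AP is the mean of the interpolated
precision max_{r' >= r} p(r') sampled at the 11 recall points
{0, 0.1, ..., 1.0}.  AP is kept in [0, 1] internally; multiply by 100 for
the percentage scale used in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxes import Box, iou

__all__ = ["MatchResult", "match_detections", "ap_11point", "evaluate_detections"]

RECALL_POINTS = np.linspace(0.0, 1.0, 11)


@dataclass
class MatchResult:
    """TP/FP flags in descending-score order plus the implied PR curve."""

    tp_flags: np.ndarray
    n_ground_truth: int
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.tp_flags = np.asarray(self.tp_flags, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def fp(self) -> int:
        return int((~self.tp_flags).sum())

    @property
    def fn(self) -> int:
        return self.n_ground_truth - self.tp

    def pr_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative (recall, precision) after each prediction."""
        cum_tp = np.cumsum(self.tp_flags)
        ranks = np.arange(1, len(self.tp_flags) + 1)
        precision = cum_tp / ranks
        recall = cum_tp / max(self.n_ground_truth, 1)
        return recall, precision

    @staticmethod
    def merge(results: Sequence["MatchResult"]) -> "MatchResult":
        """Pool per-image results into one score-ordered result."""
        scores = np.concatenate([r.scores for r in results]) if results else np.empty(0)
        flags = (
            np.concatenate([r.tp_flags for r in results]) if results else np.empty(0, bool)
        )
        order = np.argsort(-scores, kind="stable")
        return MatchResult(
            tp_flags=flags[order],
            n_ground_truth=sum(r.n_ground_truth for r in results),
            scores=scores[order],
        )


def match_detections(
    predictions: Sequence[Box],
    ground_truth: Sequence[Box],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching in descending score order.

    A prediction is a TP iff its best-IoU *unmatched* ground truth reaches
    the threshold.  Score ties break by input order, IoU ties by lowest
    ground-truth index.
    """
    if any(p.score is None for p in predictions):
        raise ValueError("all predictions must carry a score")
    order = sorted(range(len(predictions)), key=lambda i: -float(predictions[i].score))
    matched = [False] * len(ground_truth)
    flags = np.zeros(len(predictions), dtype=bool)
    scores = np.empty(len(predictions))
    for rank, idx in enumerate(order):
        pred = predictions[idx]
        scores[rank] = pred.score
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(ground_truth):
            if matched[j]:
                continue
            overlap = iou(pred, gt)
            if overlap > best_iou:
                best_iou, best_j = overlap, j
        if best_j >= 0 and best_iou >= iou_threshold:
            flags[rank] = True
            matched[best_j] = True
    return MatchResult(tp_flags=flags, n_ground_truth=len(ground_truth), scores=scores)


def ap_11point(match: MatchResult) -> float:
    """11-point interpolated average precision in [0, 1].

    For each r in {0, 0.1, ..., 1.0} the interpolated precision is the
    maximum precision over curve points with recall >= r (0 when no point
    reaches r); AP is their mean.
    """
    if match.n_ground_truth == 0:
        raise ValueError("AP undefined without ground truth (recall has no denominator)")
    recall, precision = match.pr_curve()
    total = 0.0
    for r in RECALL_POINTS:
        mask = recall >= r - 1e-12
        total += float(precision[mask].max()) if mask.any() else 0.0
    return total / 11.0


def evaluate_detections(
    per_image: Sequence[tuple[Sequence[Box], Sequence[Box]]],
    iou_threshold: float = 0.5,
) -> dict:
    """AP / precision / recall over a dataset of (predictions, ground_truth)."""
    results = [
        match_detections(preds, gts, iou_threshold) for preds, gts in per_image
    ]
    merged = MatchResult.merge(results)
    n_pred = len(merged.tp_flags)
    return {
        "ap": ap_11point(merged),
        "precision": merged.tp / n_pred if n_pred else 0.0,
        "recall": merged.tp / merged.n_ground_truth if merged.n_ground_truth else 0.0,
        "tp": merged.tp,
        "fp": merged.fp,
        "fn": merged.fn,
    }
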