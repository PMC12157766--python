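"""Axis-aligned bounding boxes and the labeled-dataset containers.

Coordinates are continuous, 0-based and half-open: a box covers
``[x_min, x_max) x [y_min, y_max)`` with x = column and y = row.  All
internal computation works in absolute pixels; normalized coordinates
appear only at the YOLO I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "ImageRecord",
    "LabeledDataset",
    "iou",
    "pairwise_iou",
    "clip_box",
    "nms",
]


@dataclass(frozen=True)
class Box:
    """A detection / annotation box, optionally carrying a confidence score.

    ``score`` is ``None`` for ground truth and a float in [0, 1] for
    predictions and pseudo-labels.  A single foreground class (pig, id 0)
    is used throughout; ``class_id`` is kept for plumbing.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float | None = None
    class_id: int = 0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def shifted(self, dx: float, dy: float) -> "Box":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )

    def corners(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def pairwise_iou(boxes_a: Sequence[Box], boxes_b: Sequence[Box]) -> np.ndarray:
    out = np.zeros((len(boxes_a), len(boxes_b)))
    for i, a in enumerate(boxes_a):
        for j, b in enumerate(boxes_b):
            out[i, j] = iou(a, b)
    return out


def clip_box(box: Box, width: float, height: float) -> Box | None:
    """Clip a box to image bounds; returns None when nothing remains."""
    x1 = max(box.x_min, 0.0)
    y1 = max(box.y_min, 0.0)
    x2 = min(box.x_max, float(width))
    y2 = min(box.y_max, float(height))
    if x2 - x1 <= 0.0 or y2 - y1 <= 0.0:
        return None
    return replace(box, x_min=x1, y_min=y1, x_max=x2, y_max=y2)


def nms(boxes: Sequence[Box], iou_threshold: float = 0.5) -> list[Box]:
    """Greedy score-descending non-maximum suppression.

    Ties in score are broken by input order (stable sort), so the result is
    deterministic.  Every box must carry a score.
    """
    order = sorted(range(len(boxes)), key=lambda i: -float(boxes[i].score))
    kept: list[Box] = []
    for i in order:
        candidate = boxes[i]
        if all(iou(candidate, k) <= iou_threshold for k in kept):
            kept.append(candidate)
    return kept


@dataclass
class ImageRecord:
    """A frame with its pixel data (8-bit grayscale or RGB)."""

    image_id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixel data must be 2-D grayscale or 3-D RGB")
        if self.pixels.size == 0:
            raise ValueError("empty image")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass
class LabeledDataset:
    """Ordered images paired with ground-truth (or pseudo-label) boxes."""

    records: list[tuple[ImageRecord, list[Box]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rec.image_id for rec, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate image_ids in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def images(self) -> list[ImageRecord]:
        return [rec for rec, _ in self.records]

    def image_ids(self) -> list[str]:
        return [rec.image_id for rec, _ in self.records]

    @staticmethod
    def concat(*datasets: "LabeledDataset") -> "LabeledDataset":
        records: list[tuple[ImageRecord, list[Box]]] = []
        for ds in datasets:
            records.extend(ds.records)
        return LabeledDataset(records)


def as_scored(boxes: Iterable[Box], score: float = 1.0) -> list[Box]:
    """Attach a uniform score to unscored boxes (testing convenience)."""
    return [replace(b, score=score if b.score is None else b.score) for b in boxes]
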