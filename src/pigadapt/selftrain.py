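"""Iterative self-training with data-distillation ensembling.

Each iteration predicts on every unlabeled target frame under five
geometric views (identity, horizontal flip, vertical flip, both flips,
90° rotation), maps all boxes back to the original frame, merges them
with greedy NMS keeping each cluster's highest-confidence box, keeps
boxes with confidence >= τ_conf as pseudo-labels (the super-low default
τ_conf = 0.01 deliberately admits weak detections — after the
augmentation-search stage the base model is strong enough that they are
informative), and continues training the same model on
source ∪ SLOT ∪ pseudo-labeled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .boxes import Box, ImageRecord, LabeledDataset, nms
from .detector import Detector
from .metrics import evaluate_detections

__all__ = [
    "ViewTransform",
    "SelfTrainConfig",
    "default_transforms",
    "map_boxes_inverse",
    "dd_predict",
    "filter_pseudo_labels",
    "self_train",
]


@dataclass(frozen=True)
class ViewTransform:
    """A geometric view: image map plus the exact inverse box map.

    ``forward_image`` maps the original pixel array to the view;
    ``inverse_box`` maps a box predicted in the view back to original
    coordinates, given the ORIGINAL width and height.  The round trip
    inverse(forward(box)) is exact for all in-bounds boxes.
    """

    name: str
    forward_image: Callable[[np.ndarray], np.ndarray]
    inverse_box: Callable[[Box, int, int], Box]
    forward_box: Callable[[Box, int, int], Box]


def _remap(b: Box, x1, y1, x2, y2) -> Box:
    return Box(x1, y1, x2, y2, score=b.score, class_id=b.class_id)


def _identity_box(b: Box, w: int, h: int) -> Box:
    return b


def _fliph_box(b: Box, w: int, h: int) -> Box:
    return _remap(b, w - b.x_max, b.y_min, w - b.x_min, b.y_max)


def _flipv_box(b: Box, w: int, h: int) -> Box:
    return _remap(b, b.x_min, h - b.y_max, b.x_max, h - b.y_min)


def _fliphv_box(b: Box, w: int, h: int) -> Box:
    return _remap(b, w - b.x_max, h - b.y_max, w - b.x_min, h - b.y_min)


def _rot90_forward_box(b: Box, w: int, h: int) -> Box:
    # clockwise: (x, y) -> (h - y, x); the view frame is h wide, w tall
    return _remap(b, h - b.y_max, b.x_min, h - b.y_min, b.x_max)


def _rot90_inverse_box(b: Box, w: int, h: int) -> Box:
    # inverse (counter-clockwise): (x', y') -> (y', h - x')
    return _remap(b, b.y_min, h - b.x_max, b.y_max, h - b.x_min)


def _rot90ccw_forward_box(b: Box, w: int, h: int) -> Box:
    # counter-clockwise: (x, y) -> (y, w - x)
    return _remap(b, b.y_min, w - b.x_max, b.y_max, w - b.x_min)


def _rot90ccw_inverse_box(b: Box, w: int, h: int) -> Box:
    return _remap(b, w - b.y_max, b.x_min, w - b.y_min, b.x_max)


def default_transforms(rot90_direction: str = "cw") -> list[ViewTransform]:
    """The five data-distillation views.

    ``rot90_direction`` selects the rotation sense of the fifth view
    (clockwise by default).
    """
    views = [
        ViewTransform("identity", lambda a: a, _identity_box, _identity_box),
        ViewTransform("flipH", lambda a: a[:, ::-1].copy(), _fliph_box, _fliph_box),
        ViewTransform("flipV", lambda a: a[::-1, :].copy(), _flipv_box, _flipv_box),
        ViewTransform(
            "flipHV", lambda a: a[::-1, ::-1].copy(), _fliphv_box, _fliphv_box
        ),
    ]
    if rot90_direction == "cw":
        views.append(
            ViewTransform(
                "rot90",
                lambda a: np.rot90(a, k=-1).copy(),
                _rot90_inverse_box,
                _rot90_forward_box,
            )
        )
    elif rot90_direction == "ccw":
        views.append(
            ViewTransform(
                "rot90",
                lambda a: np.rot90(a, k=1).copy(),
                _rot90ccw_inverse_box,
                _rot90ccw_forward_box,
            )
        )
    else:
        raise ValueError("rot90_direction must be 'cw' or 'ccw'")
    return views


@dataclass
class SelfTrainConfig:
    iterations: int = 5
    epochs_per_iteration: int = 5
    tau_conf: float = 0.01
    nms_iou: float = 0.5
    patience: int | None = None
    rot90_direction: str = "cw"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.tau_conf <= 1.0:
            raise ValueError("tau_conf must be in [0, 1]")


def map_boxes_inverse(
    transform: ViewTransform, boxes: Sequence[Box], width: int, height: int
) -> list[Box]:
    """Map boxes predicted in a transformed view back to original coordinates.

    ``width`` and ``height`` are the ORIGINAL image dimensions; for the
    rot90 view the boxes live in a height x width frame.
    """
    view_w, view_h = (
        (height, width) if transform.name == "rot90" else (width, height)
    )
    mapped = []
    for b in boxes:
        if b.x_min < 0 or b.y_min < 0 or b.x_max > view_w or b.y_max > view_h:
            raise ValueError(f"box {b.corners()} outside the {transform.name} view")
        mapped.append(transform.inverse_box(b, width, height))
    return mapped


def dd_predict(
    detector: Detector,
    image: ImageRecord | np.ndarray,
    transforms: Sequence[ViewTransform] | None = None,
    nms_iou: float = 0.5,
) -> list[Box]:
    """Multi-view ensemble prediction.

    Predicts on every transformed view, back-maps all boxes, pools them
    and keeps the NMS survivors with their own (maximum) scores.
    """
    if transforms is None:
        transforms = default_transforms()
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    h, w = pixels.shape[:2]
    pooled: list[Box] = []
    for view in transforms:
        view_pixels = view.forward_image(pixels)
        preds = detector.predict(view_pixels)
        pooled.extend(map_boxes_inverse(view, preds, w, h))
    return nms(pooled, nms_iou)


def filter_pseudo_labels(boxes: Sequence[Box], tau_conf: float) -> list[Box]:
    """Keep boxes with confidence >= tau_conf (inclusive boundary)."""
    if any(b.score is None for b in boxes):
        raise ValueError("pseudo-label candidates must carry scores")
    return [b for b in boxes if b.score >= tau_conf]


def self_train(
    detector: Detector,
    source: LabeledDataset,
    slot: LabeledDataset,
    unlabeled_target: Sequence[ImageRecord],
    config: SelfTrainConfig | None = None,
    test_set: LabeledDataset | None = None,
) -> tuple[Detector, list[dict]]:
    """Iterative self-training of an already-trained base detector.

    Pseudo-labels are regenerated with the *current* model at the start of
    every iteration; the same model state then continues training on
    source ∪ SLOT ∪ pseudo-labeled data.  Returns the final model and a
    per-iteration log (pseudo-label counts, plus test AP when a labeled
    test set is supplied).
    """
    if len(unlabeled_target) == 0:
        raise ValueError("self-training requires unlabeled target images")
    config = config or SelfTrainConfig()
    transforms = default_transforms(config.rot90_direction)
    log: list[dict] = []
    for iteration in range(1, config.iterations + 1):
        pseudo_records = []
        n_boxes = 0
        for record in unlabeled_target:
            boxes = filter_pseudo_labels(
                dd_predict(detector, record, transforms, config.nms_iou),
                config.tau_conf,
            )
            n_boxes += len(boxes)
            # every frame stays in the set, even with zero surviving boxes
            pseudo_records.append(
                (ImageRecord(f"pseudo_{record.image_id}", record.pixels), boxes)
            )
        pseudo = LabeledDataset(pseudo_records)
        train_set = LabeledDataset.concat(source, slot, pseudo)
        train_log = detector.train(
            train_set,
            max_epochs=config.epochs_per_iteration,
            patience=config.patience,
        )
        entry = {
            "iteration": iteration,
            "pseudo_boxes": n_boxes,
            "epochs_trained": train_log.epochs_trained,
        }
        if test_set is not None:
            entry["test_ap"] = evaluate_detections(
                [(detector.predict(rec), gts) for rec, gts in test_set]
            )["ap"]
        log.append(entry)
    return detector, log
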