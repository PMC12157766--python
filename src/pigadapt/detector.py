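"""The trainable-detector contract and a deterministic CPU reference detector.

The adaptation pipeline (augmentation search, self-training) is detector
agnostic: it only requires the :class:`Detector` behavioral contract —
``train(dataset, max_epochs, patience)`` and ``predict(image)`` returning
scored boxes, with bit-reproducible behavior for identical inputs.  Deep
models plug in through the same contract via :func:`register_detector`.

The built-in reference detector is a background-subtraction blob detector:
it estimates a per-shape mean background from its training images,
thresholds the absolute difference at an intensity θ, and reports
8-connected components above a minimum area as boxes.  Its "training" is
an honest epoch loop — each epoch evaluates one θ candidate from a
coarse-to-fine schedule, the retained θ maximizes AP on a deterministic
80/20 train split, and the validation loss (1 − AP on the held-out split)
drives standard early stopping.  That gives the search and self-training
stages real train/early-stop semantics on one CPU.
"""

from __future__ import annotations

import copy
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .boxes import Box, ImageRecord, LabeledDataset
from .keyframe import _to_gray
from .metrics import MatchResult, ap_11point, match_detections

__all__ = [
    "Detector",
    "TrainLog",
    "ReferenceDetector",
    "register_detector",
    "make_detector",
    "available_detectors",
]


@dataclass
class TrainLog:
    """Per-epoch record of a training run."""

    val_losses: list[float] = field(default_factory=list)
    epochs_trained: int = 0
    stopped_early: bool = False


class Detector(ABC):
    """Behavioral contract every pluggable detector must satisfy."""

    @abstractmethod
    def train(
        self,
        dataset: LabeledDataset,
        max_epochs: int = 30,
        patience: int | None = 3,
    ) -> TrainLog:
        """Fit (or continue fitting) on a labeled dataset.

        Training uses a deterministic 80/20 train/validation split and
        stops early when the validation loss fails to decrease for
        ``patience`` consecutive epochs (``None`` disables early stopping).
        """

    @abstractmethod
    def predict(self, image: ImageRecord | np.ndarray) -> list[Box]:
        """Scored detections for one image; deterministic per trained state."""

    def clone_state(self) -> "Detector":
        """Deep copy, so self-training snapshots are independent."""
        return copy.deepcopy(self)


def _split_indices(n: int) -> tuple[list[int], list[int]]:
    """Deterministic 80/20 split: every 5th record validates."""
    val = list(range(4, n, 5))
    train = [i for i in range(n) if (i - 4) % 5 != 0]
    if not val and n > 1:
        val = [n - 1]
        train = list(range(n - 1))
    if not train:
        train = list(range(n))
    return train, val


def _theta_schedule(max_epochs: int) -> list[float]:
    """Coarse-to-fine θ candidates over [0, 255] (deterministic).

    Dyadic refinement: 128, then 64/192, then 32/96/160/224, … — every
    epoch halves the resolution of the explored grid, so successive
    epochs genuinely refine the fit and a validation-loss plateau is a
    meaningful early-stop signal.
    """
    schedule: list[float] = []
    step = 128
    while len(schedule) < max_epochs and step >= 1:
        schedule.extend(float(t) for t in range(step, 256, 2 * step))
        step //= 2
    return schedule[:max_epochs]


def _refine_schedule(theta0: float, max_epochs: int) -> list[float]:
    """Candidates around an already-fitted θ (continued training).

    Continuing training must not restart the coarse sweep: the first
    epoch re-evaluates the current θ under the new data, later epochs
    probe symmetric offsets of shrinking, then growing, radius.
    """
    offsets = [0.0]
    for radius in (10.0, 5.0, 2.0, 1.0, 15.0, 20.0, 30.0, 40.0, 60.0, 80.0):
        offsets.extend((radius, -radius))
    seen: set[float] = set()
    schedule: list[float] = []
    for off in offsets:
        theta = theta0 + off
        if 0.0 <= theta <= 255.0 and theta not in seen:
            seen.add(theta)
            schedule.append(theta)
        if len(schedule) >= max_epochs:
            break
    return schedule[:max_epochs]


#: improvements smaller than this (in AP) are treated as ties: a challenger
#: θ must beat the incumbent by a material margin, and a validation-loss
#: change below it does not reset early-stopping patience
MIN_DELTA = 1e-3


class ReferenceDetector(Detector):
    """Background-subtraction connected-components detector.

    Parameters
    ----------
    min_area:
        Components below this pixel area are discarded as noise specks.
    background:
        Optional fixed background image (typically the cumulative-moving-
        average of the monitored pen).  Its shape is pinned: training
        never re-estimates it, but still estimates mean backgrounds for
        training images of other shapes (e.g. source pens recorded at a
        different resolution).
    """

    def __init__(self, min_area: float = 50.0, background: np.ndarray | None = None):
        if min_area < 0:
            raise ValueError("min_area must be nonnegative")
        self.min_area = float(min_area)
        self.theta: float | None = None
        self.backgrounds: dict[tuple[int, int], np.ndarray] = {}
        self.pinned_shapes: set[tuple[int, int]] = set()
        if background is not None:
            background = np.asarray(background, dtype=np.float64)
            if background.ndim == 3:
                background = background[..., :3] @ np.array([0.299, 0.587, 0.114])
            self.backgrounds[background.shape] = background
            self.pinned_shapes.add(background.shape)

    # -- prediction ---------------------------------------------------------

    def _background_for(self, shape: tuple[int, int]) -> np.ndarray:
        if not self.backgrounds:
            raise ValueError("detector has no background model; train first")
        if shape in self.backgrounds:
            return self.backgrounds[shape]
        # Fall back to resizing the closest-sized stored background.
        key = min(
            self.backgrounds,
            key=lambda k: abs(k[0] * k[1] - shape[0] * shape[1]),
        )
        return resize(self.backgrounds[key], shape, order=1, preserve_range=True)

    def predict(self, image: ImageRecord | np.ndarray) -> list[Box]:
        if self.theta is None:
            raise ValueError("detector not trained (θ unset)")
        pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
        gray = _to_gray(pixels)
        background = self._background_for(gray.shape)
        diff = np.abs(gray - background)
        return self._boxes_from_diff(diff, self.theta)

    def _boxes_from_diff(self, diff: np.ndarray, theta: float) -> list[Box]:
        mask = diff >= theta
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        boxes: list[Box] = []
        for lab, slc in enumerate(ndimage.find_objects(labels), start=1):
            if slc is None:
                continue
            ys, xs = slc
            # component pixel area, not bbox area
            area = int(np.count_nonzero(labels[ys, xs] == lab))
            if area < self.min_area:
                continue
            score = float(np.clip(diff[ys, xs].mean() / 255.0, 0.0, 1.0))
            if score <= 0.0:
                score = 1e-6
            boxes.append(
                Box(float(xs.start), float(ys.start), float(xs.stop), float(ys.stop),
                    score=score)
            )
        return boxes

    # -- training -----------------------------------------------------------

    def train(
        self,
        dataset: LabeledDataset,
        max_epochs: int = 30,
        patience: int | None = 3,
    ) -> TrainLog:
        if len(dataset) == 0:
            raise ValueError("empty training dataset")
        if all(len(boxes) == 0 for _, boxes in dataset):
            raise ValueError("training dataset has no ground-truth boxes")
        train_idx, val_idx = _split_indices(len(dataset))

        # Background: per-shape per-pixel median over the training-split
        # images (robust to the animals present in every frame).  A shape's
        # background is fitted the first time the shape is seen and kept
        # on continued-training calls — like converged early layers — and
        # an injected CMA background is never re-estimated.
        grays = [_to_gray(rec.pixels) for rec, _ in dataset.records]
        stacks: dict[tuple[int, int], list[np.ndarray]] = {}
        for i in train_idx:
            g = grays[i]
            if g.shape in self.backgrounds:
                continue
            stacks.setdefault(g.shape, []).append(g)
        for shape, stack in stacks.items():
            self.backgrounds[shape] = np.median(np.stack(stack), axis=0)

        # Precompute |image - background| once; epochs only re-threshold.
        diffs = [np.abs(g - self._background_for(g.shape)) for g in grays]

        def split_ap(theta: float, indices: Sequence[int]) -> float:
            results: list[MatchResult] = []
            for i in indices:
                preds = self._boxes_from_diff(diffs[i], theta)
                results.append(match_detections(preds, dataset.records[i][1]))
            merged = MatchResult.merge(results)
            if merged.n_ground_truth == 0:
                return 0.0
            return ap_11point(merged)

        log = TrainLog()
        best_train_ap = -1.0
        best_theta = self.theta if self.theta is not None else 10.0
        best_val_loss = np.inf
        stall = 0
        schedule = (
            _theta_schedule(max_epochs)
            if self.theta is None
            else _refine_schedule(self.theta, max_epochs)
        )
        for theta in schedule:
            log.epochs_trained += 1
            train_ap = split_ap(theta, train_idx)
            if train_ap > best_train_ap + MIN_DELTA:
                best_train_ap = train_ap
                best_theta = theta
            val_loss = 1.0 - split_ap(best_theta, val_idx)
            log.val_losses.append(val_loss)
            if val_loss < best_val_loss - MIN_DELTA:
                best_val_loss = val_loss
                stall = 0
            else:
                stall += 1
                if patience is not None and stall >= patience:
                    log.stopped_early = True
                    break
        self.theta = best_theta
        return log


    # -- persistence --------------------------------------------------------

    def save_state(self, path) -> None:
        """Serialize θ, min_area and the per-shape backgrounds (npz)."""
        arrays = {}
        pinned = []
        for i, (shape, bg) in enumerate(self.backgrounds.items()):
            arrays[f"bg_{i}"] = bg
            pinned.append(shape in self.pinned_shapes)
        np.savez(
            path,
            theta=np.float64(-1.0 if self.theta is None else self.theta),
            min_area=np.float64(self.min_area),
            pinned=np.array(pinned, dtype=bool),
            **arrays,
        )

    @staticmethod
    def load_state(path) -> "ReferenceDetector":
        data = np.load(path)
        detector = ReferenceDetector(min_area=float(data["min_area"]))
        theta = float(data["theta"])
        detector.theta = None if theta < 0 else theta
        pinned = data["pinned"]
        for i in range(len(pinned)):
            bg = data[f"bg_{i}"]
            detector.backgrounds[bg.shape] = bg
            if pinned[i]:
                detector.pinned_shapes.add(bg.shape)
        return detector


# -- registry ---------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., Detector]] = {}


def register_detector(name: str, factory: Callable[..., Detector]) -> None:
    """Register a detector factory under a config-selectable name."""
    _REGISTRY[name] = factory


def make_detector(name: str, **kwargs) -> Detector:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown detector {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)


def available_detectors() -> list[str]:
    return sorted(_REGISTRY)


register_detector("reference", ReferenceDetector)
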