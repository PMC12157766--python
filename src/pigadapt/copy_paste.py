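"""Copy-and-paste synthesis of the augmentation-search evaluation set.

Objects are cropped out of the single annotated target frame (the SLOT
image) and pasted onto the object-free cumulative-moving-average
background at random positions and counts.  The resulting labeled images
are the fitness-evaluation data for the augmentation search: they share
the target domain's appearance but are generated through a path disjoint
from any augmented training image.

Polygon mode composites each object through a mask instead of pasting the
full rectangle.  SLOT annotations carry only boxes, so without polygon
labels the mask falls back to the box's inscribed ellipse — pigs are
roughly elliptical, and the ellipse removes rectangular paste seams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import Box, ImageRecord, LabeledDataset, clip_box, iou

__all__ = [
    "ObjectPatch",
    "PasteConfig",
    "extract_objects",
    "synthesize_eval_image",
    "build_eval_set",
    "ellipse_mask",
    "polygon_mask",
]


@dataclass
class ObjectPatch:
    """A cropped object with an optional compositing mask."""

    pixels: np.ndarray
    mask: np.ndarray | None
    source_box: Box

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask dimensions must equal patch dimensions")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class PasteConfig:
    """Controls for evaluation-set synthesis."""

    n_images: int = 100
    objects_per_image: tuple[int, int] = (5, 30)
    max_pairwise_iou: float = 0.3
    mode: str = "polygon"
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        lo, hi = self.objects_per_image
        if lo > hi or lo < 0:
            raise ValueError("objects_per_image range is empty")
        if not 0.0 <= self.max_pairwise_iou <= 1.0:
            raise ValueError("max_pairwise_iou must be in [0, 1]")
        if self.mode not in ("bbox", "polygon"):
            raise ValueError(f"unknown paste mode {self.mode!r}")


def ellipse_mask(height: int, width: int) -> np.ndarray:
    """Boolean mask of the axis-aligned ellipse inscribed in (height, width)."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry, rx = height / 2.0, width / 2.0
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def polygon_mask(height: int, width: int, polygon: Sequence[tuple[float, float]]) -> np.ndarray:
    """Rasterize an (x, y) polygon into a boolean mask."""
    from skimage.draw import polygon as sk_polygon

    xs = np.array([p[0] for p in polygon])
    ys = np.array([p[1] for p in polygon])
    rr, cc = sk_polygon(ys, xs, shape=(height, width))
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cc] = True
    return mask


def extract_objects(
    slot_image: ImageRecord,
    boxes: Sequence[Box],
    mode: str = "polygon",
    polygons: Sequence[Sequence[tuple[float, float]]] | None = None,
) -> list[ObjectPatch]:
    """Crop one patch per annotated box from the SLOT image.

    In polygon mode a mask is attached: a rasterized polygon when polygon
    labels are supplied (coordinates relative to the box origin), else the
    inscribed-ellipse fallback.
    """
    import warnings

    pixels = slot_image.pixels
    patches: list[ObjectPatch] = []
    for i, box in enumerate(boxes):
        clipped = clip_box(box, slot_image.width, slot_image.height)
        if clipped is None:
            warnings.warn(f"box #{i} outside image after clipping; skipped")
            continue
        y1, y2 = int(round(clipped.y_min)), int(round(clipped.y_max))
        x1, x2 = int(round(clipped.x_min)), int(round(clipped.x_max))
        y2, x2 = max(y2, y1 + 1), max(x2, x1 + 1)
        patch = pixels[y1:y2, x1:x2].copy()
        mask = None
        if mode == "polygon":
            if polygons is not None and polygons[i] is not None:
                mask = polygon_mask(patch.shape[0], patch.shape[1], polygons[i])
            else:
                mask = ellipse_mask(patch.shape[0], patch.shape[1])
        patches.append(ObjectPatch(pixels=patch, mask=mask, source_box=clipped))
    return patches


def _paste(
    canvas: np.ndarray, patch: ObjectPatch, x: int, y: int, use_mask: bool
) -> None:
    h, w = patch.pixels.shape[:2]
    region = canvas[y : y + h, x : x + w]
    if use_mask and patch.mask is not None:
        region[patch.mask] = patch.pixels[patch.mask]
    else:
        region[:] = patch.pixels


def synthesize_eval_image(
    background: np.ndarray,
    patches: Sequence[ObjectPatch],
    config: PasteConfig,
    rng: np.random.Generator,
    image_id: str = "cp_0",
    forced_placements: Sequence[tuple[int, int, int]] | None = None,
) -> tuple[ImageRecord, list[Box]]:
    """Paste randomly chosen patches onto the background.

    The object count is uniform over ``objects_per_image``; each placement
    is uniform over valid positions and rejected while its IoU with any
    already placed box exceeds ``max_pairwise_iou`` (up to
    ``max_attempts`` tries, then the object is skipped).
    ``forced_placements`` — (patch index, x, y) triples — bypasses the
    random placement for testing.
    """
    bh, bw = background.shape[:2]
    for p in patches:
        if p.height > bh or p.width > bw:
            raise ValueError(
                f"patch {p.width}x{p.height} larger than background {bw}x{bh}"
            )
    canvas = background.astype(np.float64).copy()
    placed: list[Box] = []
    if forced_placements is not None:
        chosen = forced_placements
        for idx, x, y in chosen:
            patch = patches[idx]
            _paste(canvas, patch, x, y, config.mode == "polygon")
            placed.append(Box(float(x), float(y), float(x + patch.width), float(y + patch.height)))
        return ImageRecord(image_id, np.clip(canvas, 0, 255)), placed

    lo, hi = config.objects_per_image
    n_objects = int(rng.integers(lo, hi + 1))
    for _ in range(n_objects):
        patch = patches[int(rng.integers(len(patches)))]
        for _attempt in range(config.max_attempts):
            x = int(rng.integers(0, bw - patch.width + 1))
            y = int(rng.integers(0, bh - patch.height + 1))
            candidate = Box(float(x), float(y), float(x + patch.width), float(y + patch.height))
            if all(iou(candidate, b) <= config.max_pairwise_iou for b in placed):
                _paste(canvas, patch, x, y, config.mode == "polygon")
                placed.append(candidate)
                break
    return ImageRecord(image_id, np.clip(canvas, 0, 255)), placed


def build_eval_set(
    background: np.ndarray,
    patches: Sequence[ObjectPatch],
    config: PasteConfig | None = None,
) -> LabeledDataset:
    """n_images independently synthesized labeled images (seeded)."""
    if config is None:
        config = PasteConfig()
    if not patches:
        raise ValueError("no object patches to paste")
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_images):
        record, boxes = synthesize_eval_image(
            background, patches, config, rng, image_id=f"cp_{i:04d}"
        )
        records.append((record, boxes))
    return LabeledDataset(records)
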