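"""The 8-gene augmentation policy and its application to the SLOT image.

A policy (chromosome) controls how many augmented copies of the single
annotated target frame are produced and which transforms each copy
receives:

==========  =====================================  ======================
gene        meaning                                admissible values
==========  =====================================  ======================
n_image     number of augmented images             integers 10–500
p_zoom_in   probability of whole-frame zoom-in     0.0–0.5, step 0.1
m_zoom_in   zoom-in magnification                  1.2–1.9, step 0.1
p_zoom_out  probability of whole-frame zoom-out    0.0–0.5, step 0.1
m_zoom_out  zoom-out magnification                 0.2–0.9, step 0.1
f_trans     per-object transform flag              0 original, 1 translateX,
                                                   2 translateY, 3 rotate,
                                                   4 shear, 5 flipH, 6 flipV
p_trans     per-object transform probability       0.1–1.0, step 0.1
m_trans     transform magnitude                    integers 1–8
==========  =====================================  ======================

Flag-conditional constraints: ``f_trans=0`` fixes ``p_trans=1`` and
``m_trans=1`` (they have no effect); flips (5, 6) fix ``m_trans=1``.
The probability of leaving a frame unzoomed is derived, never searched:
``p_original = 1 − p_zoom_in − p_zoom_out``.

Zoom-in/-out act on the whole frame; the flagged transform acts on each
object independently.  The magnitude→parameter mapping is linear
(RandAugment-style): translate shifts by ``round(0.05·m · object size)``
pixels, rotation angle is ``3.75°·m`` (30° at m=8), shear factor is
``0.04·m`` (0.32 at m=8); flips ignore the magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.transform import AffineTransform, rescale, rotate as sk_rotate, warp

from .boxes import Box, ImageRecord, LabeledDataset, clip_box

__all__ = [
    "Chromosome",
    "SearchSpace",
    "derive_p_original",
    "apply_frame_zoom",
    "apply_object_transform",
    "augment_slot",
    "FLAG_NAMES",
]

FLAG_NAMES = {
    0: "original",
    1: "translateX",
    2: "translateY",
    3: "rotate",
    4: "shear",
    5: "flipH",
    6: "flipV",
}

GENE_NAMES = (
    "n_image",
    "p_zoom_in",
    "m_zoom_in",
    "p_zoom_out",
    "m_zoom_out",
    "f_trans",
    "p_trans",
    "m_trans",
)


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class Chromosome:
    """One augmentation policy; gene order follows :data:`GENE_NAMES`."""

    n_image: int
    p_zoom_in: float
    m_zoom_in: float
    p_zoom_out: float
    m_zoom_out: float
    f_trans: int
    p_trans: float
    m_trans: int

    def genes(self) -> tuple:
        return tuple(getattr(self, g) for g in GENE_NAMES)

    def to_json(self) -> str:
        return json.dumps(dict(zip(GENE_NAMES, self.genes())))

    @staticmethod
    def from_json(text: str) -> "Chromosome":
        return Chromosome(**json.loads(text))

    @staticmethod
    def from_genes(genes: Sequence) -> "Chromosome":
        return Chromosome(**dict(zip(GENE_NAMES, genes)))


@dataclass(frozen=True)
class SearchSpace:
    """Per-gene admissible grids plus the flag-conditional rules."""

    n_image_values: tuple[int, ...] = tuple(range(10, 501))
    p_zoom_in_values: tuple[float, ...] = _grid(0.0, 0.5, 0.1)
    m_zoom_in_values: tuple[float, ...] = _grid(1.2, 1.9, 0.1)
    p_zoom_out_values: tuple[float, ...] = _grid(0.0, 0.5, 0.1)
    m_zoom_out_values: tuple[float, ...] = _grid(0.2, 0.9, 0.1)
    f_trans_values: tuple[int, ...] = tuple(range(7))
    p_trans_values: tuple[float, ...] = _grid(0.1, 1.0, 0.1)
    m_trans_values: tuple[int, ...] = tuple(range(1, 9))

    def __post_init__(self) -> None:
        for name in GENE_NAMES:
            if not getattr(self, f"{name}_values"):
                raise ValueError(f"empty grid for gene {name}")

    @staticmethod
    def miniature(n_image_max: int = 60) -> "SearchSpace":
        """A desk-scale space: identical grids but few augmented images."""
        return SearchSpace(n_image_values=tuple(range(10, n_image_max + 1)))

    def grid(self, gene: str) -> tuple:
        return getattr(self, f"{gene}_values")

    def repair(self, chromosome: Chromosome) -> Chromosome:
        """Apply the flag-conditional gene fixings."""
        if chromosome.f_trans == 0:
            return replace(chromosome, p_trans=1.0, m_trans=1)
        if chromosome.f_trans in (5, 6):
            return replace(chromosome, m_trans=1)
        return chromosome

    def validate(self, chromosome: Chromosome) -> None:
        for gene in GENE_NAMES:
            value = getattr(chromosome, gene)
            if value not in self.grid(gene):
                raise ValueError(f"gene {gene}={value!r} outside its grid")
        if chromosome.f_trans == 0 and (
            chromosome.p_trans != 1.0 or chromosome.m_trans != 1
        ):
            raise ValueError("f_trans=0 requires p_trans=1 and m_trans=1")
        if chromosome.f_trans in (5, 6) and chromosome.m_trans != 1:
            raise ValueError("flip flags require m_trans=1")
        if chromosome.p_zoom_in + chromosome.p_zoom_out > 1.0 + 1e-9:
            raise ValueError("p_zoom_in + p_zoom_out must not exceed 1")

    def sample(self, rng: np.random.Generator) -> Chromosome:
        genes = [self.grid(g)[int(rng.integers(len(self.grid(g))))] for g in GENE_NAMES]
        return self.repair(Chromosome.from_genes(genes))


def derive_p_original(chromosome: Chromosome) -> float:
    """Probability that a frame keeps its original scale."""
    return 1.0 - chromosome.p_zoom_in - chromosome.p_zoom_out


# ---------------------------------------------------------------------------
# frame-level zoom
# ---------------------------------------------------------------------------


def _map_point(p: float, c: float, m: float) -> float:
    return (p - c) * m + c


def apply_frame_zoom(
    image: np.ndarray,
    boxes: Sequence[Box],
    kind: str,
    magnitude: float,
    space: SearchSpace | None = None,
    min_visible_fraction: float = 0.25,
) -> tuple[np.ndarray, list[Box]]:
    """Zoom the whole frame in or out about its center.

    Zoom-in scales content by M and crops back to the original size; boxes
    map through p → (p − c)·M + c and are dropped when less than
    ``min_visible_fraction`` of their scaled area survives the crop.
    Zoom-out shrinks content to M·size and letterboxes it centered on a
    canvas of the original size filled with the per-image mean intensity.
    """
    space = space or SearchSpace()
    grid = space.m_zoom_in_values if kind == "in" else space.m_zoom_out_values
    if kind not in ("in", "out"):
        raise ValueError(f"zoom kind must be 'in' or 'out', got {kind!r}")
    if round(float(magnitude), 10) not in grid:
        raise ValueError(f"zoom-{kind} magnitude {magnitude} outside the search grid")

    arr = np.asarray(image, dtype=np.float64)
    h, w = arr.shape[:2]
    m = float(magnitude)
    scaled = rescale(arr, m, order=1, preserve_range=True, channel_axis=-1 if arr.ndim == 3 else None)
    sh, sw = scaled.shape[:2]

    if kind == "in":
        y0 = (sh - h) // 2
        x0 = (sw - w) // 2
        out = scaled[y0 : y0 + h, x0 : x0 + w]
        cy, cx = h / 2.0, w / 2.0
        mapped: list[Box] = []
        for b in boxes:
            nb = Box(
                _map_point(b.x_min, cx, m),
                _map_point(b.y_min, cy, m),
                _map_point(b.x_max, cx, m),
                _map_point(b.y_max, cy, m),
                score=b.score,
                class_id=b.class_id,
            )
            clipped = clip_box(nb, w, h)
            if clipped is not None and clipped.area >= min_visible_fraction * nb.area:
                mapped.append(clipped)
        return out, mapped

    out = np.full_like(arr, arr.mean())
    y0 = (h - sh) // 2
    x0 = (w - sw) // 2
    out[y0 : y0 + sh, x0 : x0 + sw] = scaled
    ox = (w - m * w) / 2.0
    oy = (h - m * h) / 2.0
    mapped = []
    for b in boxes:
        nb = Box(
            b.x_min * m + ox,
            b.y_min * m + oy,
            b.x_max * m + ox,
            b.y_max * m + oy,
            score=b.score,
            class_id=b.class_id,
        )
        clipped = clip_box(nb, w, h)
        if clipped is not None:
            mapped.append(clipped)
    return out, mapped


# ---------------------------------------------------------------------------
# per-object transforms
# ---------------------------------------------------------------------------


def translate_shift(magnitude: int, extent: float) -> int:
    """Pixel shift for translate at magnitude m: round(0.05·m·extent)."""
    return int(round(0.05 * magnitude * extent))


def rotate_angle(magnitude: int) -> float:
    """Rotation angle in degrees: 3.75°·m (30° at m=8)."""
    return 3.75 * magnitude


def shear_factor(magnitude: int) -> float:
    """Horizontal shear factor: 0.04·m (0.32 at m=8)."""
    return 0.04 * magnitude


def _int_box(box: Box) -> tuple[int, int, int, int]:
    x1 = int(np.floor(box.x_min))
    y1 = int(np.floor(box.y_min))
    x2 = max(int(np.ceil(box.x_max)), x1 + 1)
    y2 = max(int(np.ceil(box.y_max)), y1 + 1)
    return x1, y1, x2, y2


def _vacate(
    canvas: np.ndarray,
    x1: int,
    y1: int,
    x2: int,
    y2: int,
    background: np.ndarray | None,
) -> None:
    """Fill the vacated object region from the background model.

    Without a background the region is filled with the mean of the one-pixel
    ring just outside the box (edge-replicate fill).
    """
    if background is not None and background.shape[:2] == canvas.shape[:2]:
        canvas[y1:y2, x1:x2] = background[y1:y2, x1:x2]
        return
    h, w = canvas.shape[:2]
    ry1, ry2 = max(y1 - 1, 0), min(y2 + 1, h)
    rx1, rx2 = max(x1 - 1, 0), min(x2 + 1, w)
    ring = canvas[ry1:ry2, rx1:rx2].copy()
    inner = np.zeros(ring.shape[:2], dtype=bool)
    inner[y1 - ry1 : y1 - ry1 + (y2 - y1), x1 - rx1 : x1 - rx1 + (x2 - x1)] = True
    border = ring[~inner]
    fill = border.mean(axis=0) if border.size else canvas.mean(axis=(0, 1))
    canvas[y1:y2, x1:x2] = fill


def _composite(
    canvas: np.ndarray,
    patch: np.ndarray,
    mask: np.ndarray,
    cx: float,
    cy: float,
) -> None:
    """Paste patch centered at (cx, cy), clipped to canvas bounds."""
    ph, pw = patch.shape[:2]
    x1 = int(round(cx - pw / 2.0))
    y1 = int(round(cy - ph / 2.0))
    gx1, gy1 = max(x1, 0), max(y1, 0)
    gx2 = min(x1 + pw, canvas.shape[1])
    gy2 = min(y1 + ph, canvas.shape[0])
    if gx2 <= gx1 or gy2 <= gy1:
        return
    sub_patch = patch[gy1 - y1 : gy2 - y1, gx1 - x1 : gx2 - x1]
    sub_mask = mask[gy1 - y1 : gy2 - y1, gx1 - x1 : gx2 - x1]
    region = canvas[gy1:gy2, gx1:gx2]
    region[sub_mask] = sub_patch[sub_mask]


def apply_object_transform(
    image: np.ndarray,
    boxes: Sequence[Box],
    flag: int,
    magnitude: int,
    rng: np.random.Generator | None = None,
    background: np.ndarray | None = None,
    transform_mask: Sequence[bool] | None = None,
) -> tuple[np.ndarray, list[Box]]:
    """Apply the flagged transform independently to each object.

    Each object's patch is cropped, transformed, and re-composited at the
    (possibly shifted) location; the vacated pixels are filled from the
    background model when available.  ``transform_mask`` selects which
    objects are transformed (all by default); untouched objects keep their
    boxes verbatim.
    """
    if flag not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"invalid transform flag {flag}")
    if flag in (5, 6):
        if magnitude != 1:
            raise ValueError("flips require magnitude 1")
    elif magnitude not in range(1, 9):
        raise ValueError(f"invalid magnitude {magnitude} (expected 1-8)")
    canvas = np.asarray(image, dtype=np.float64).copy()
    h, w = canvas.shape[:2]
    out_boxes: list[Box] = []
    for i, box in enumerate(boxes):
        if transform_mask is not None and not transform_mask[i]:
            out_boxes.append(box)
            continue
        x1, y1, x2, y2 = _int_box(clip_box(box, w, h) or box)
        patch = canvas[y1:y2, x1:x2].copy()
        ph, pw = patch.shape[:2]
        cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0

        if flag == 5:  # flipH: mirror in place, box unchanged
            canvas[y1:y2, x1:x2] = patch[:, ::-1]
            out_boxes.append(box)
            continue
        if flag == 6:  # flipV
            canvas[y1:y2, x1:x2] = patch[::-1, :]
            out_boxes.append(box)
            continue

        _vacate(canvas, x1, y1, x2, y2, background)

        if flag in (1, 2):
            extent = box.width if flag == 1 else box.height
            shift = translate_shift(magnitude, extent)
            dx, dy = (shift, 0) if flag == 1 else (0, shift)
            full_mask = np.ones((ph, pw), dtype=bool)
            _composite(canvas, patch, full_mask, cx + dx, cy + dy)
            moved = clip_box(box.shifted(dx, dy), w, h)
            if moved is not None:
                out_boxes.append(moved)
            continue

        if flag == 3:
            angle = rotate_angle(magnitude)
            rotated = _rotate_patch(patch, angle)
            valid = _rotate_patch(np.ones((ph, pw)), angle) > 0.5
            _composite(canvas, rotated, valid, cx, cy)
            rad = np.deg2rad(angle)
            new_w = pw * abs(np.cos(rad)) + ph * abs(np.sin(rad))
            new_h = pw * abs(np.sin(rad)) + ph * abs(np.cos(rad))
        else:  # flag == 4, shear
            k = shear_factor(magnitude)
            sheared, valid = _shear_patch(patch, k)
            _composite(canvas, sheared, valid, cx, cy)
            new_w = pw + k * ph
            new_h = float(ph)
        nb = Box(cx - new_w / 2.0, cy - new_h / 2.0, cx + new_w / 2.0, cy + new_h / 2.0,
                 score=box.score, class_id=box.class_id)
        clipped = clip_box(nb, w, h)
        if clipped is not None:
            out_boxes.append(clipped)
    return canvas, out_boxes


def _rotate_patch(patch: np.ndarray, angle: float) -> np.ndarray:
    return sk_rotate(patch, angle, resize=True, order=1, preserve_range=True, cval=0.0)


def _shear_patch(patch: np.ndarray, k: float) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal shear x' = x + k·(h − y); returns (pixels, valid mask)."""
    ph, pw = patch.shape[:2]
    out_w = int(np.ceil(pw + k * ph))
    # inverse map for warp: source = A^{-1} · dest
    tform = AffineTransform(matrix=np.array([[1.0, -k, k * ph], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))
    sheared = warp(
        patch, tform.inverse, output_shape=(ph, out_w), order=1,
        preserve_range=True, cval=0.0,
    )
    valid = warp(
        np.ones((ph, pw)), tform.inverse, output_shape=(ph, out_w), order=1,
        preserve_range=True, cval=0.0,
    ) > 0.5
    return sheared, valid


# ---------------------------------------------------------------------------
# policy application
# ---------------------------------------------------------------------------


def augment_slot(
    slot_image: ImageRecord,
    slot_boxes: Sequence[Box],
    chromosome: Chromosome,
    background: np.ndarray | None = None,
    seed: int = 0,
    space: SearchSpace | None = None,
) -> LabeledDataset:
    """Produce ``n_image`` augmented copies of the SLOT frame.

    For every output image one frame-level op is drawn from
    {zoom-in, zoom-out, original} with probabilities
    (p_zoom_in, p_zoom_out, 1 − p_zoom_in − p_zoom_out); the per-object
    transform ``f_trans`` is then applied independently to each object
    with probability ``p_trans``.  Fully deterministic given the seed.
    """
    space = space or SearchSpace()
    rng = np.random.default_rng(seed)
    records = []
    base = np.asarray(slot_image.pixels, dtype=np.float64)
    for i in range(chromosome.n_image):
        img = base.copy()
        boxes = list(slot_boxes)
        u = rng.random()
        if u < chromosome.p_zoom_in:
            img, boxes = apply_frame_zoom(img, boxes, "in", chromosome.m_zoom_in, space)
        elif u < chromosome.p_zoom_in + chromosome.p_zoom_out:
            img, boxes = apply_frame_zoom(img, boxes, "out", chromosome.m_zoom_out, space)
        if chromosome.f_trans != 0 and boxes:
            mask = rng.random(len(boxes)) < chromosome.p_trans
            if mask.any():
                img, boxes = apply_object_transform(
                    img,
                    boxes,
                    chromosome.f_trans,
                    chromosome.m_trans,
                    rng=rng,
                    background=background,
                    transform_mask=list(mask),
                )
        record = ImageRecord(
            image_id=f"aug_{slot_image.image_id}_{i:04d}",
            pixels=np.clip(img, 0.0, 255.0),
        )
        records.append((record, boxes))
    return LabeledDataset(records)
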