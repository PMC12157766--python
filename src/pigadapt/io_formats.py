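"""Reading and writing frames, annotations and configuration.

Two annotation dialects are supported:

* YOLO-txt — one object per line, ``class cx cy w h``, all values
  normalized to [0, 1] by the image size.
* COCO-JSON — the standard ``images`` / ``annotations`` / ``categories``
  layout with ``bbox = [x, y, w, h]`` in absolute pixels.

Boxes are converted to absolute corner coordinates at read time and
clipped to the image bounds; boxes left with nonpositive area are dropped
with a warning.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import imageio.v3 as iio
import numpy as np

from .boxes import Box, ImageRecord, clip_box

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


class AnnotationParseError(ValueError):
    """Raised for malformed annotation records; names the offending line."""


def _require_size(image_size: tuple[int, int] | None) -> tuple[int, int]:
    if image_size is None:
        raise ValueError("image_size=(width, height) is required for the yolo dialect")
    width, height = image_size
    if width < 1 or height < 1:
        raise ValueError("image_size must be positive")
    return int(width), int(height)


def _finalize(raw: Box, image_size: tuple[int, int] | None, where: str) -> Box | None:
    if image_size is not None:
        clipped = clip_box(raw, image_size[0], image_size[1])
    else:
        clipped = raw
    if clipped is None:
        warnings.warn(f"dropping zero-area box after clipping at {where}")
        return None
    return clipped


def read_annotations(
    path: str | Path,
    dialect: str,
    image_size: tuple[int, int] | None = None,
) -> list[Box]:
    """Read one annotation file and return absolute-pixel corner boxes."""
    path = Path(path)
    if dialect == "yolo":
        width, height = _require_size(image_size)
        boxes: list[Box] = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 5 fields, got {len(parts)}"
                )
            try:
                class_id = int(parts[0])
                cx, cy, w, h = (float(v) for v in parts[1:])
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if w <= 0 or h <= 0:
                warnings.warn(f"dropping nonpositive-size box at {path}:{lineno}")
                continue
            raw = Box(
                x_min=(cx - w / 2) * width,
                y_min=(cy - h / 2) * height,
                x_max=(cx + w / 2) * width,
                y_max=(cy + h / 2) * height,
                class_id=class_id,
            )
            box = _finalize(raw, (width, height), f"{path}:{lineno}")
            if box is not None:
                boxes.append(box)
        return boxes
    if dialect == "coco":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise AnnotationParseError(f"{path}: invalid JSON: {exc}") from exc
        sizes = {
            img["id"]: (img.get("width"), img.get("height"))
            for img in doc.get("images", [])
        }
        boxes = []
        for idx, ann in enumerate(doc.get("annotations", [])):
            try:
                x, y, w, h = ann["bbox"]
            except (KeyError, ValueError) as exc:
                raise AnnotationParseError(
                    f"{path}: annotation #{idx}: bad bbox field ({exc})"
                ) from exc
            if w <= 0 or h <= 0:
                warnings.warn(f"dropping nonpositive-size bbox at {path} annotation #{idx}")
                continue
            size = sizes.get(ann.get("image_id"))
            if size is None or size[0] is None:
                size = image_size
            raw = Box(x, y, x + w, y + h, class_id=int(ann.get("category_id", 0)))
            box = _finalize(raw, size, f"{path}: annotation #{idx}")
            if box is not None:
                boxes.append(box)
        return boxes
    raise ValueError(f"unknown dialect {dialect!r} (expected 'yolo' or 'coco')")


def write_annotations(
    boxes: Sequence[Box],
    path: str | Path,
    dialect: str,
    image_size: tuple[int, int] | None = None,
    image_id: str = "image",
    precision: int = 6,
) -> None:
    """Write boxes in the named dialect; inverse of :func:`read_annotations`."""
    path = Path(path)
    if dialect == "yolo":
        width, height = _require_size(image_size)
        lines = []
        for b in boxes:
            cx = (b.x_min + b.x_max) / 2 / width
            cy = (b.y_min + b.y_max) / 2 / height
            w = (b.x_max - b.x_min) / width
            h = (b.y_max - b.y_min) / height
            lines.append(
                f"{b.class_id} {cx:.{precision}f} {cy:.{precision}f} "
                f"{w:.{precision}f} {h:.{precision}f}"
            )
        path.write_text("".join(line + "\n" for line in lines))
        return
    if dialect == "coco":
        width, height = image_size if image_size is not None else (None, None)
        doc = {
            "images": [
                {"id": 0, "file_name": image_id, "width": width, "height": height}
            ],
            "annotations": [
                {
                    "id": i,
                    "image_id": 0,
                    "category_id": b.class_id,
                    "bbox": [b.x_min, b.y_min, b.width, b.height],
                    "area": b.area,
                    "iscrowd": 0,
                    **({"score": b.score} if b.score is not None else {}),
                }
                for i, b in enumerate(boxes)
            ],
            "categories": [{"id": 0, "name": "pig"}],
        }
        path.write_text(json.dumps(doc, indent=1))
        return
    raise ValueError(f"unknown dialect {dialect!r} (expected 'yolo' or 'coco')")


def _natural_key(name: str) -> tuple:
    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", name)
    )


def load_frame_sequence(path: str | Path) -> Iterator[ImageRecord]:
    """Yield frames from a directory (filename order) or a video file.

    Directory frames are ordered by natural sort of the filename, so
    ``f_2.png`` precedes ``f_10.png``; the order is deterministic across
    repeated calls.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=lambda p: _natural_key(p.name),
        )
        for p in files:
            try:
                pixels = iio.imread(p)
            except Exception as exc:  # noqa: BLE001 - reported with frame name
                raise IOError(f"cannot decode frame {p}: {exc}") from exc
            yield ImageRecord(image_id=p.stem, pixels=pixels)
        return
    if path.is_file():
        try:
            for idx, frame in enumerate(iio.imiter(path)):
                yield ImageRecord(image_id=f"{path.stem}_{idx:06d}", pixels=frame)
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"cannot decode video {path}: {exc}") from exc
        return
    raise FileNotFoundError(path)


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    """Save an image, round-half-even quantizing real-valued arrays to 8 bit."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def save_dataset(
    dataset,
    out_dir: str | Path,
    dialects: Iterable[str] = ("yolo", "coco"),
) -> None:
    """Write a LabeledDataset as PNG images plus per-image annotation files."""
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    for dialect in dialects:
        (out_dir / f"labels_{dialect}").mkdir(parents=True, exist_ok=True)
    for record, boxes in dataset:
        save_image(record.pixels, images_dir / f"{record.image_id}.png")
        size = (record.width, record.height)
        for dialect in dialects:
            suffix = "txt" if dialect == "yolo" else "json"
            write_annotations(
                boxes,
                out_dir / f"labels_{dialect}" / f"{record.image_id}.{suffix}",
                dialect,
                image_size=size,
                image_id=record.image_id,
            )
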