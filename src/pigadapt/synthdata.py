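"""Synthetic pigpen scenes, domain pairs and videos with ground truth.

The generator emulates the structure of infrared pen footage with simple,
controllable primitives: bright elliptical blobs (pigs) on a darker
textured background.  Two domains are modeled:

* ``top`` view, ``day`` illumination — the source domain: uniform object
  scale, brighter background.
* ``tilted`` view, ``night`` illumination — the target domain: object
  size shrinks linearly toward the image top (the far side of a tilted
  camera) and the scene is darker with reduced contrast.

Videos are mostly static — each object moves with a small probability per
frame (pigs rest ~80% of the time) — with a slow illumination drift so
the per-frame entropy actually varies.

Everything is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from scipy import ndimage

from .boxes import Box, ImageRecord, LabeledDataset, clip_box, iou

__all__ = [
    "SceneConfig",
    "generate_scene",
    "generate_domain_pair",
    "generate_video",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one scene distribution.

    Semi-axis ranges are in pixels before the viewpoint scale gradient;
    ``tilt_min_scale`` is the object scale factor at the very top of a
    tilted image (1.0 at the bottom).  ``contrast_range`` is the object
    brightness above the local background; night illumination multiplies
    background level and contrast by ``night_factor``.
    """

    width: int = 192
    height: int = 192
    n_objects: tuple[int, int] = (5, 30)
    viewpoint: str = "top"  # "top" | "tilted"
    illumination: str = "day"  # "day" | "night"
    semi_minor: tuple[float, float] = (5.0, 8.0)
    semi_major: tuple[float, float] = (8.0, 12.0)
    contrast_range: tuple[float, float] = (80.0, 140.0)
    background_level: float = 60.0
    texture_amplitude: float = 5.0
    night_factor: float = 0.8
    tilt_min_scale: float = 0.65
    max_pairwise_iou: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.viewpoint not in ("top", "tilted"):
            raise ValueError(f"unknown viewpoint {self.viewpoint!r}")
        if self.illumination not in ("day", "night"):
            raise ValueError(f"unknown illumination {self.illumination!r}")
        if self.n_objects[0] < 0 or self.n_objects[0] > self.n_objects[1]:
            raise ValueError("invalid object count range")
        if not 0.0 < self.tilt_min_scale <= 1.0:
            raise ValueError("tilt_min_scale must be in (0, 1]")


def _illumination(config: SceneConfig) -> tuple[float, float]:
    """(background level, contrast multiplier) for the configured lighting."""
    if config.illumination == "night":
        return config.background_level * config.night_factor, config.night_factor
    return config.background_level, 1.0


def _textured_background(
    config: SceneConfig, rng: np.random.Generator, level: float
) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, size=(config.height, config.width))
    texture = ndimage.gaussian_filter(noise, sigma=3.0)
    scale = texture.std()
    if scale > 0:
        texture = texture / scale * config.texture_amplitude
    return level + texture


def _scale_at(config: SceneConfig, y: float) -> float:
    if config.viewpoint == "top":
        return 1.0
    g = config.tilt_min_scale
    return g + (1.0 - g) * (y / max(config.height - 1, 1))


def _draw_ellipse(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    a: float,
    b: float,
    angle: float,
    brightness: float,
    base_level: float,
) -> Box | None:
    """Add one soft-edged ellipse; returns its tight bounding box."""
    h, w = canvas.shape
    cos, sin = np.cos(angle), np.sin(angle)
    # tight axis-aligned extent of the rotated ellipse
    ex = np.sqrt((b * cos) ** 2 + (a * sin) ** 2)
    ey = np.sqrt((b * sin) ** 2 + (a * cos) ** 2)
    x1, x2 = cx - ex, cx + ex
    y1, y2 = cy - ey, cy + ey
    gx1, gy1 = max(int(np.floor(x1)), 0), max(int(np.floor(y1)), 0)
    gx2, gy2 = min(int(np.ceil(x2)) + 1, w), min(int(np.ceil(y2)) + 1, h)
    if gx2 <= gx1 or gy2 <= gy1:
        return None
    yy, xx = np.mgrid[gy1:gy2, gx1:gx2]
    u = (xx - cx) * cos + (yy - cy) * sin
    v = -(xx - cx) * sin + (yy - cy) * cos
    r2 = (u / b) ** 2 + (v / a) ** 2
    inside = r2 <= 1.0
    # soft shading: brighter at the blob center, like a lit pig back
    shade = np.clip(1.0 - 0.35 * r2, 0.0, 1.0)
    region = canvas[gy1:gy2, gx1:gx2]
    lit = base_level + brightness * shade
    region[inside] = np.maximum(region[inside], lit[inside])
    box = Box(x1, y1, x2, y2)
    return clip_box(box, w, h)


def generate_scene(
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    image_id: str = "scene",
    n_objects: int | None = None,
    object_states: list[dict] | None = None,
    level_offset: float = 0.0,
    background: np.ndarray | None = None,
) -> tuple[ImageRecord, list[Box]]:
    """One scene with tight ground-truth boxes.

    ``n_objects`` overrides the configured count range; ``object_states``
    (as produced by :func:`_sample_objects`) renders a fixed object set
    and ``background`` a fixed backdrop — the video generator uses both
    for temporal persistence.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    level, contrast_mult = _illumination(config)
    if background is None:
        canvas = _textured_background(config, rng, level + level_offset)
    else:
        canvas = background.astype(np.float64) + level_offset
    if object_states is None:
        if n_objects is None:
            lo, hi = config.n_objects
            n_objects = int(rng.integers(lo, hi + 1))
        object_states = _sample_objects(config, rng, n_objects, contrast_mult)
    boxes: list[Box] = []
    for state in object_states:
        scale = _scale_at(config, state["cy"])
        box = _draw_ellipse(
            canvas,
            state["cx"],
            state["cy"],
            state["a"] * scale,
            state["b"] * scale,
            state["angle"],
            state["contrast"],
            level + level_offset,
        )
        if box is not None:
            boxes.append(box)
    pixels = np.clip(canvas, 0.0, 255.0).astype(np.uint8)
    return ImageRecord(image_id, pixels), boxes


def _sample_objects(
    config: SceneConfig,
    rng: np.random.Generator,
    n_objects: int,
    contrast_mult: float,
    max_attempts: int = 200,
) -> list[dict]:
    """Sample object states, rejecting placements that overlap too much.

    After ``max_attempts`` rejections the overlap cap is waived so the
    requested count is always honored (pigs do pile up).
    """
    states: list[dict] = []
    placed: list[Box] = []
    for _ in range(n_objects):
        state = None
        for attempt in range(max_attempts + 1):
            a = rng.uniform(*config.semi_minor)
            b = rng.uniform(*config.semi_major)
            cx = rng.uniform(b, config.width - b)
            cy = rng.uniform(b, config.height - b)
            angle = rng.uniform(0.0, np.pi)
            scale = _scale_at(config, cy)
            ext = b * scale
            candidate = Box(cx - ext, cy - ext, cx + ext, cy + ext)
            if attempt == max_attempts or all(
                iou(candidate, p) <= config.max_pairwise_iou for p in placed
            ):
                placed.append(candidate)
                state = {
                    "cx": cx,
                    "cy": cy,
                    "a": a,
                    "b": b,
                    "angle": angle,
                    "contrast": rng.uniform(*config.contrast_range) * contrast_mult,
                }
                break
        states.append(state)
    return states


def generate_scene_dataset(
    config: SceneConfig, n_images: int, seed: int, prefix: str = "img"
) -> LabeledDataset:
    """n independent scenes from one distribution (convenience wrapper)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_images):
        record, boxes = generate_scene(config, rng, image_id=f"{prefix}_{i:04d}")
        records.append((record, boxes))
    return LabeledDataset(records)


def generate_domain_pair(
    source_config: SceneConfig | None = None,
    target_config: SceneConfig | None = None,
    n_source: int = 40,
    n_target_labeled_test: int = 30,
    n_target_unlabeled: int = 60,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, list[ImageRecord]]:
    """Disjoint (source train, target test, target unlabeled) collections.

    Defaults realize the studied shift: top-view day source versus
    tilted-view night target; the unlabeled pool and the test set share
    the target distribution.
    """
    if source_config is None:
        source_config = SceneConfig(viewpoint="top", illumination="day")
    if target_config is None:
        target_config = SceneConfig(viewpoint="tilted", illumination="night")
    if (
        source_config.viewpoint == target_config.viewpoint
        and source_config.illumination == target_config.illumination
    ):
        raise ValueError("source and target configs must differ in viewpoint or illumination")
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    source = generate_scene_dataset(source_config, n_source, seeds[0], "src")
    target_test = generate_scene_dataset(
        target_config, n_target_labeled_test, seeds[1], "tgt_test"
    )
    unlabeled_ds = generate_scene_dataset(
        target_config, n_target_unlabeled, seeds[2], "tgt_unl"
    )
    return source, target_test, unlabeled_ds.images()


def generate_video(
    config: SceneConfig | None = None,
    n_frames: int = 100,
    move_probability: float = 0.2,
    rng: np.random.Generator | None = None,
    step_scale: float = 8.0,
    drift_depth: float = 0.25,
    drift_cycles: float = 2.0,
    vary_count: bool = True,
) -> Iterator[tuple[ImageRecord, list[Box]]]:
    """A mostly-static video with persistent objects and ground truth.

    Objects persist across frames; each frame every object independently
    moves (a Gaussian step of scale ``step_scale`` px) with
    ``move_probability``, else stays put.  With ``vary_count`` the number
    of visible animals tracks a slow activity cycle between the ends of
    the configured count range (one enters or leaves per frame toward the
    cycle's target) — crowded frames carry visibly higher intensity
    entropy, the property key-frame selection exploits.  Illumination
    follows the same ``drift_cycles`` cycles, dipping to
    ``1 - drift_depth`` of full brightness (``drift_depth=0`` disables
    the dimming)."""
    if config is None:
        config = SceneConfig(viewpoint="tilted", illumination="night")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    level, contrast_mult = _illumination(config)
    lo, hi = config.n_objects
    n_objects = int(rng.integers(lo, hi + 1))
    states = _sample_objects(config, rng, n_objects, contrast_mult)
    texture = _textured_background(config, rng, level)
    for i in range(n_frames):
        phase = 2.0 * np.pi * drift_cycles * i / max(n_frames, 2)
        if i > 0 and vary_count:
            activity = 0.5 - 0.5 * np.cos(phase)
            target_count = int(round(lo + (hi - lo) * activity))
            if len(states) < target_count:
                states.extend(_sample_objects(config, rng, 1, contrast_mult))
            elif len(states) > max(target_count, 1):
                states.pop(int(rng.integers(len(states))))
        if i > 0 and move_probability > 0:
            for state in states:
                if rng.random() < move_probability:
                    state["cx"] = float(
                        np.clip(state["cx"] + rng.normal(0, step_scale), state["b"], config.width - state["b"])
                    )
                    state["cy"] = float(
                        np.clip(state["cy"] + rng.normal(0, step_scale), state["b"], config.height - state["b"])
                    )
                    state["angle"] = float((state["angle"] + rng.normal(0, 0.4)) % np.pi)
        # bright when the pen is active, dim when it rests (aligned cycles)
        gain = 1.0 - drift_depth * (0.5 + 0.5 * np.cos(phase))
        record, boxes = generate_scene(
            config,
            rng,
            image_id=f"frame_{i:05d}",
            object_states=states,
            background=texture,
        )
        if drift_depth > 0.0:
            record = ImageRecord(
                record.image_id,
                np.clip(np.rint(record.pixels.astype(np.float64) * gain), 0, 255).astype(np.uint8),
            )
        yield record, boxes
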