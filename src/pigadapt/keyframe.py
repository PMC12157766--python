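"""Entropy-based key-frame extraction and SLOT selection.

A frame's information content is summarized by the Shannon entropy of its
256-bin grayscale intensity histogram.  Mostly-static surveillance video
(pigs rest for roughly 80% of the day) is compressed by storing a frame
only when its entropy differs from the last *stored* frame's entropy by at
least a threshold.  The single frame with the highest entropy — typically
the busiest scene — is the SLOT (Single Label On Target) frame, the one
image a human annotates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .boxes import ImageRecord

__all__ = [
    "EntropySeries",
    "KeyframeConfig",
    "frame_entropy",
    "build_entropy_series",
    "select_keyframes",
    "select_slot",
]

#: ITU-R BT.601 luma weights used to collapse RGB to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class KeyframeConfig:
    """Tunables for key-frame selection.

    tau_ent is compared against the absolute entropy difference on the
    normalized scale; ``normalization='bits_over_8'`` divides the raw
    Shannon entropy (bits) by 8, the maximum for 256 bins, mapping it to
    [0, 1].  ``raw_bits`` keeps the entropy in bits.
    """

    tau_ent: float = 0.05
    normalization: str = "bits_over_8"

    def __post_init__(self) -> None:
        if self.tau_ent < 0:
            raise ValueError("tau_ent must be >= 0")
        if self.normalization not in ("bits_over_8", "raw_bits"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class EntropySeries:
    """Per-frame entropies with their frame identifiers."""

    values: np.ndarray
    frame_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.frame_ids:
            self.frame_ids = [str(i) for i in range(len(self.values))]
        if len(self.frame_ids) != len(self.values):
            raise ValueError("frame_ids and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        return pixels[..., :3].astype(float) @ _LUMA
    return pixels.astype(float)


def frame_entropy(
    image: ImageRecord | np.ndarray, normalization: str = "bits_over_8"
) -> float:
    """Normalized intensity entropy of one frame.

    The grayscale image is histogrammed over the 256 8-bit intensity bins,
    and the Shannon entropy -sum p(l) log2 p(l) of the bin probabilities is
    returned (0*log 0 := 0), divided by 8 under ``bits_over_8``.
    """
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    if pixels.size == 0:
        raise ValueError("cannot compute entropy of an empty image")
    gray = _to_gray(pixels)
    levels = np.clip(np.rint(gray), 0, 255).astype(np.int64)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy_bits = max(float(-(nz * np.log2(nz)).sum()), 0.0)
    if normalization == "bits_over_8":
        return entropy_bits / 8.0
    if normalization == "raw_bits":
        return entropy_bits
    raise ValueError(f"unknown normalization {normalization!r}")


def build_entropy_series(
    frames: Iterable[ImageRecord], normalization: str = "bits_over_8"
) -> EntropySeries:
    values: list[float] = []
    ids: list[str] = []
    for frame in frames:
        values.append(frame_entropy(frame, normalization))
        ids.append(frame.image_id)
    return EntropySeries(np.asarray(values), ids)


def select_keyframes(
    series: EntropySeries | Sequence[float], config: KeyframeConfig | None = None
) -> list[int]:
    """Indices of frames whose entropy jumps by >= tau_ent from the reference.

    Frame 0 is always stored and initializes the reference entropy; frame i
    is stored iff |e_i - e_ref| >= tau_ent, and the reference is updated to
    e_i only upon storage (sticky reference).  The comparison is inclusive
    so that tau_ent = 0 degenerates to selecting every frame.
    """
    if config is None:
        config = KeyframeConfig()
    values = series.values if isinstance(series, EntropySeries) else np.asarray(series)
    if len(values) == 0:
        raise ValueError("empty entropy series")
    selected = [0]
    ref = float(values[0])
    for i in range(1, len(values)):
        if abs(float(values[i]) - ref) >= config.tau_ent:
            selected.append(i)
            ref = float(values[i])
    return selected


def select_slot(series: EntropySeries | Sequence[float]) -> int:
    """Index of the maximum-entropy frame; ties break to the earliest."""
    values = series.values if isinstance(series, EntropySeries) else np.asarray(series)
    if len(values) == 0:
        raise ValueError("empty entropy series")
    return int(np.argmax(values))
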