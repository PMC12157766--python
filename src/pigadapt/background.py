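"""Object-free background estimation via the cumulative moving average.

Averaging a long, mostly static video per pixel makes moving animals fade
out, leaving a clean pen background.  The mean is accumulated in streaming
fashion (Welford-style running mean in double precision) so arbitrarily
long frame sequences never need to be stacked in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .boxes import ImageRecord

__all__ = ["BackgroundModel", "cma_background"]


@dataclass
class BackgroundModel:
    """Streaming per-pixel mean over frames of identical dimensions."""

    mean: np.ndarray | None = field(default=None)
    frame_count: int = 0

    def update(self, frame: ImageRecord | np.ndarray) -> None:
        pixels = frame.pixels if isinstance(frame, ImageRecord) else np.asarray(frame)
        pixels = pixels.astype(np.float64)
        if self.mean is None:
            self.mean = pixels.copy()
            self.frame_count = 1
            return
        if pixels.shape != self.mean.shape:
            name = frame.image_id if isinstance(frame, ImageRecord) else "<array>"
            raise ValueError(
                f"frame {name}: dimensions {pixels.shape} do not match "
                f"background {self.mean.shape}"
            )
        self.frame_count += 1
        self.mean += (pixels - self.mean) / self.frame_count

    @property
    def background(self) -> np.ndarray:
        if self.mean is None:
            raise ValueError("no frames consumed")
        return self.mean


def cma_background(frames: Iterable[ImageRecord | np.ndarray]) -> np.ndarray:
    """Per-pixel arithmetic mean over all frames, computed streaming.

    Numerically equal (to ~1e-9) to the batch mean; raises on an empty
    sequence or a mid-stream dimension change.
    """
    model = BackgroundModel()
    for frame in frames:
        model.update(frame)
    if model.frame_count == 0:
        raise ValueError("cma_background requires at least one frame")
    return model.background
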