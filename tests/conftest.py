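"""Shared fixtures: small synthetic datasets and a scripted mock detector."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pigadapt.boxes import Box, ImageRecord, LabeledDataset
from pigadapt.detector import Detector, TrainLog

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_blob_image(
    boxes: list[Box],
    width: int = 64,
    height: int = 64,
    background: float = 30.0,
    contrast: float = 200.0,
    image_id: str = "blob",
) -> ImageRecord:
    """Flat background with bright rectangles at the given boxes."""
    pixels = np.full((height, width), background)
    for b in boxes:
        pixels[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)] = (
            background + contrast
        )
    return ImageRecord(image_id, np.clip(pixels, 0, 255).astype(np.uint8))


@pytest.fixture()
def separable_dataset(rng) -> LabeledDataset:
    """High-contrast rectangular blobs on a flat background: a detector
    with any reasonable threshold separates them perfectly."""
    records = []
    for i in range(10):
        boxes = []
        for _ in range(3):
            x = int(rng.integers(2, 40))
            y = int(rng.integers(2, 40))
            w = int(rng.integers(8, 14))
            h = int(rng.integers(8, 14))
            candidate = Box(x, y, x + w, y + h)
            if all(
                candidate.x_max + 2 < b.x_min
                or b.x_max + 2 < candidate.x_min
                or candidate.y_max + 2 < b.y_min
                or b.y_max + 2 < candidate.y_min
                for b in boxes
            ):
                boxes.append(candidate)
        records.append((make_blob_image(boxes, image_id=f"blob_{i}"), boxes))
    return LabeledDataset(records)


class MockDetector(Detector):
    """Contract-conforming detector replaying scripted predictions.

    ``script`` maps an image key to the boxes to return; the key is the
    byte digest of the pixel array, so transformed views of an image get
    their own entries.  Unknown images yield no detections.
    """

    def __init__(self, script=None, by_id=None):
        self.script = script or {}
        self.by_id = by_id or {}
        self.train_calls: list[int] = []
        self.predict_calls = 0

    @staticmethod
    def key(pixels: np.ndarray) -> bytes:
        return np.ascontiguousarray(pixels).tobytes()

    def train(self, dataset, max_epochs=30, patience=3) -> TrainLog:
        self.train_calls.append(len(dataset))
        return TrainLog(val_losses=[0.0], epochs_trained=1)

    def predict(self, image):
        self.predict_calls += 1
        if isinstance(image, ImageRecord):
            if image.image_id in self.by_id:
                return list(self.by_id[image.image_id])
            pixels = image.pixels
        else:
            pixels = np.asarray(image)
        return list(self.script.get(self.key(pixels), []))


@pytest.fixture()
def mock_detector_cls():
    return MockDetector
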