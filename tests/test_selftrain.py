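"""View transforms, multi-view ensembling, pseudo-label filtering and the
self-training loop."""

from __future__ import annotations

import numpy as np
import pytest

from pigadapt.boxes import Box, ImageRecord, LabeledDataset
from pigadapt.selftrain import (
    SelfTrainConfig,
    dd_predict,
    default_transforms,
    filter_pseudo_labels,
    map_boxes_inverse,
    self_train,
)


def random_box(rng, w, h):
    # coordinates on a 1/8-pixel lattice: detector boxes are integral and
    # dyadic fractions keep the mirror subtractions exact in binary float
    x1 = int(rng.integers(0, 8 * (w - 1))) / 8
    y1 = int(rng.integers(0, 8 * (h - 1))) / 8
    x2 = x1 + int(rng.integers(1, 8 * w - 8 * x1)) / 8
    y2 = y1 + int(rng.integers(1, 8 * h - 8 * y1)) / 8
    return Box(x1, y1, x2, y2)


class TestViewTransforms:
    def test_five_views_with_exact_names(self):
        names = [t.name for t in default_transforms()]
        assert names == ["identity", "flipH", "flipV", "flipHV", "rot90"]

    def test_fliph_mirror_arithmetic(self):
        (t,) = [t for t in default_transforms() if t.name == "flipH"]
        (mapped,) = map_boxes_inverse(t, [Box(10, 20, 30, 40)], 100, 80)
        assert mapped.corners() == (70.0, 20.0, 90.0, 40.0)

    def test_identity_maps_box_to_itself(self):
        (t,) = [t for t in default_transforms() if t.name == "identity"]
        box = Box(3, 4, 10, 12)
        assert map_boxes_inverse(t, [box], 50, 50)[0].corners() == box.corners()

    @pytest.mark.parametrize("direction", ["cw", "ccw"])
    def test_exact_round_trip_all_transforms_500_boxes(self, direction, rng):
        w, h = 37, 23  # non-square stresses the rotation mapping
        boxes = [random_box(rng, w, h) for _ in range(500)]
        for t in default_transforms(direction):
            for box in boxes:
                forward = t.forward_box(box, w, h)
                back = t.inverse_box(forward, w, h)
                assert back.corners() == box.corners()

    def test_forward_image_and_box_consistent(self, rng):
        """A bright pixel tracked through each view lands inside the
        forward-mapped box."""
        w, h = 12, 9
        pixels = np.zeros((h, w))
        pixels[4, 7] = 255.0
        box = Box(7, 4, 8, 5)
        for t in default_transforms():
            view = t.forward_image(pixels)
            fb = t.forward_box(box, w, h)
            ys, xs = np.nonzero(view == 255.0)
            assert fb.x_min <= xs[0] < fb.x_max
            assert fb.y_min <= ys[0] < fb.y_max

    def test_out_of_bounds_box_rejected(self):
        (t,) = [t for t in default_transforms() if t.name == "flipH"]
        with pytest.raises(ValueError):
            map_boxes_inverse(t, [Box(90, 0, 110, 10)], 100, 100)


class TestDdPredict:
    def test_single_identity_view_equals_plain_predict(self, mock_detector_cls):
        img = ImageRecord("x", np.arange(100, dtype=np.uint8).reshape(10, 10))
        box = Box(1, 1, 5, 5, score=0.8)
        mock = mock_detector_cls(script={mock_detector_cls.key(img.pixels): [box]})
        identity = [t for t in default_transforms() if t.name == "identity"]
        out = dd_predict(mock, img, transforms=identity)
        assert [b.corners() for b in out] == [box.corners()]
        assert out[0].score == 0.8

    def test_nms_keeps_highest_scored_duplicate(self, mock_detector_cls):
        # a centered box is invariant under all five views; each view
        # reports it with a different confidence
        size = 100
        img = ImageRecord("c", np.zeros((size, size), dtype=np.uint8))
        scores = [0.5, 0.6, 0.4, 0.55, 0.45]
        transforms = default_transforms()
        script = {}
        mock = mock_detector_cls()
        calls = {"i": 0}

        def predict(pixels):
            s = scores[calls["i"] % 5]
            calls["i"] += 1
            return [Box(40, 40, 60, 60, score=s)]

        mock.predict = lambda image: predict(image)
        out = dd_predict(mock, img, transforms)
        assert len(out) == 1
        assert out[0].score == 0.6

    def test_disjoint_boxes_all_retained(self, mock_detector_cls):
        img = ImageRecord("d", np.zeros((100, 100), dtype=np.uint8))
        mock = mock_detector_cls()
        views = default_transforms()[:2]  # identity, flipH
        boxes_by_view = [
            [Box(0, 0, 10, 10, score=0.9)],
            [Box(60, 60, 70, 70, score=0.8)],  # flips to (30..40, 60..70)
        ]
        calls = {"i": 0}

        def predict(image):
            out = boxes_by_view[calls["i"] % 2]
            calls["i"] += 1
            return out

        mock.predict = predict
        out = dd_predict(mock, img, views)
        assert len(out) == 2


class TestFilterPseudoLabels:
    def test_inclusive_boundary(self):
        boxes = [
            Box(0, 0, 1, 1, score=0.005),
            Box(1, 1, 2, 2, score=0.01),
            Box(2, 2, 3, 3, score=0.5),
        ]
        kept = filter_pseudo_labels(boxes, 0.01)
        assert len(kept) == 2

    def test_zero_threshold_keeps_all(self):
        boxes = [Box(0, 0, 1, 1, score=s) for s in (0.0, 0.3, 1.0)]
        assert len(filter_pseudo_labels(boxes, 0.0)) == 3

    def test_lowering_threshold_gives_superset(self, rng):
        boxes = [Box(i, 0, i + 1, 1, score=float(s))
                 for i, s in enumerate(rng.random(50))]
        grid = [0.9, 0.5, 0.1, 0.05, 0.01, 0.001, 0.0]
        previous: set = set()
        for tau in grid:
            kept = {b.corners() for b in filter_pseudo_labels(boxes, tau)}
            assert previous <= kept
            previous = kept

    def test_unscored_boxes_rejected(self):
        with pytest.raises(ValueError):
            filter_pseudo_labels([Box(0, 0, 1, 1)], 0.5)


class TestSelfTrain:
    def test_empty_unlabeled_pool_errors(self, mock_detector_cls):
        ds = LabeledDataset([(ImageRecord("a", np.zeros((8, 8), dtype=np.uint8)),
                              [Box(0, 0, 2, 2)])])
        with pytest.raises(ValueError):
            self_train(mock_detector_cls(), ds, ds, [])

    def test_runs_one_train_call_per_iteration(self, mock_detector_cls):
        source = LabeledDataset([(ImageRecord("s", np.zeros((8, 8), dtype=np.uint8)),
                                  [Box(0, 0, 3, 3)])])
        slot = LabeledDataset([(ImageRecord("l", np.ones((8, 8), dtype=np.uint8)),
                                [Box(1, 1, 4, 4)])])
        unlabeled = [ImageRecord(f"u{i}", np.full((8, 8), i, dtype=np.uint8))
                     for i in range(3)]
        mock = mock_detector_cls()
        config = SelfTrainConfig(iterations=5, epochs_per_iteration=2)
        _, log = self_train(mock, source, slot, unlabeled, config)
        assert len(mock.train_calls) == 5
        # each train call sees source + slot + every unlabeled frame
        assert all(n == 1 + 1 + 3 for n in mock.train_calls)
        assert [e["iteration"] for e in log] == [1, 2, 3, 4, 5]

    def test_pseudo_labels_regenerated_each_iteration(self, mock_detector_cls):
        """A detector whose predictions change across iterations yields
        different pseudo-label counts in the log."""
        source = LabeledDataset([(ImageRecord("s", np.zeros((8, 8), dtype=np.uint8)),
                                  [Box(0, 0, 3, 3)])])
        unlabeled = [ImageRecord("u", np.full((8, 8), 7, dtype=np.uint8))]
        mock = mock_detector_cls()
        state = {"n": 0}

        def predict(image):
            return [Box(i, 0, i + 2, 2, score=0.9) for i in range(0, 2 * state["n"], 3)]

        original_train = mock.train

        def train(dataset, max_epochs=30, patience=3):
            state["n"] += 1
            return original_train(dataset, max_epochs, patience)

        mock.predict = predict
        mock.train = train
        slot = LabeledDataset([(ImageRecord("l", np.ones((8, 8), dtype=np.uint8)),
                                [Box(1, 1, 4, 4)])])
        config = SelfTrainConfig(iterations=3, epochs_per_iteration=1,
                                 nms_iou=0.9)
        _, log = self_train(mock, source, slot, unlabeled, config)
        counts = [e["pseudo_boxes"] for e in log]
        assert counts[0] != counts[-1]

    def test_test_ap_logged_when_test_set_supplied(self, mock_detector_cls):
        gt = [Box(2, 2, 6, 6)]
        test_img = ImageRecord("t", np.full((8, 8), 3, dtype=np.uint8))
        test_set = LabeledDataset([(test_img, gt)])
        mock = mock_detector_cls(
            by_id={"t": [Box(2, 2, 6, 6, score=0.9)]}
        )
        source = LabeledDataset([(ImageRecord("s", np.zeros((8, 8), dtype=np.uint8)),
                                  [Box(0, 0, 3, 3)])])
        unlabeled = [ImageRecord("u", np.full((8, 8), 9, dtype=np.uint8))]
        slot = LabeledDataset([(ImageRecord("l", np.ones((8, 8), dtype=np.uint8)),
                                [Box(1, 1, 4, 4)])])
        _, log = self_train(mock, source, slot, unlabeled,
                            SelfTrainConfig(iterations=2), test_set=test_set)
        assert all(e["test_ap"] == pytest.approx(1.0) for e in log)
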