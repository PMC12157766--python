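"""End-to-end orchestration of the adaptation pipeline.

The full procedure, given source data and an unlabeled target video:

1. per-frame entropy → key frames (entropy-difference rule);
2. SLOT = the key frame with maximum entropy, annotated (here: the
   generator's ground truth, or a user-supplied label file);
3. object-free background = cumulative moving average of all frames;
4. copy-paste evaluation set from SLOT patches on that background;
5. GA augmentation search → best policy c*;
6. base detector trained on source ∪ SLOT ∪ augment(c*);
7. self-training with data-distillation pseudo-labels on the unlabeled
   key frames;
8. 11-point-AP evaluation on a labeled target test set.

:func:`run_experiment` runs everything in memory on the synthetic domain
pair (the desk-scale analog of the full study); the CLI wraps the same
stages with file checkpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .augment import Chromosome, SearchSpace, augment_slot
from .background import cma_background
from .boxes import Box, ImageRecord, LabeledDataset
from .config import PipelineConfig
from .copy_paste import build_eval_set, extract_objects
from .das import FitnessRecord, run_das
from .detector import Detector, make_detector
from .keyframe import EntropySeries, build_entropy_series, select_keyframes, select_slot
from .metrics import evaluate_detections
from .selftrain import self_train
from .synthdata import SceneConfig, generate_domain_pair, generate_video

logger = logging.getLogger(__name__)

__all__ = ["ExperimentResult", "run_experiment", "prepare_target"]


@dataclass
class ExperimentResult:
    """Everything the end-to-end run measured, all APs in [0, 1]."""

    source_only_ap: float
    base_ap: float
    self_trained_ap: float
    best_chromosome: Chromosome
    das_log: list[FitnessRecord]
    selftrain_log: list[dict]
    n_keyframes: int
    n_video_frames: int
    slot_entropy: float
    n_test_images: int

    @property
    def adaptation_gain(self) -> float:
        return self.self_trained_ap - self.source_only_ap


@dataclass
class TargetArtifacts:
    entropy: EntropySeries
    keyframe_indices: list[int]
    slot_record: ImageRecord
    slot_boxes: list[Box]
    unlabeled: list[ImageRecord]
    background: np.ndarray


def prepare_target(
    frames_with_truth: Sequence[tuple[ImageRecord, list[Box]]],
    config: PipelineConfig,
    exclude_indices: set[int] | None = None,
) -> TargetArtifacts:
    """Stages 1-3 on a decoded target video with per-frame ground truth.

    The SLOT frame's boxes come from the supplied truth (the human
    annotation step of a real deployment); the remaining key frames form
    the unlabeled pool.  ``exclude_indices`` (e.g. held-out benchmark
    frames) are barred from both the SLOT choice and the unlabeled pool.
    """
    exclude = exclude_indices or set()
    frames = [rec for rec, _ in frames_with_truth]
    truths = [boxes for _, boxes in frames_with_truth]
    series = build_entropy_series(frames, config.entropy_normalization)
    key_idx = select_keyframes(series, config.keyframe_config())
    usable = [i for i in key_idx if i not in exclude] or key_idx
    slot_among_usable = select_slot(
        EntropySeries(series.values[usable], [series.frame_ids[i] for i in usable])
    )
    slot_idx = usable[slot_among_usable]
    unlabeled = [frames[i] for i in key_idx if i != slot_idx and i not in exclude]
    background = cma_background(frames)
    return TargetArtifacts(
        entropy=series,
        keyframe_indices=key_idx,
        slot_record=frames[slot_idx],
        slot_boxes=truths[slot_idx],
        unlabeled=unlabeled,
        background=background,
    )


def _detector_factory(config: PipelineConfig, background: np.ndarray | None = None):
    def factory() -> Detector:
        return make_detector(
            config.detector, min_area=config.detector_min_area, background=background
        )

    return factory


def _test_ap(detector: Detector, test_set: LabeledDataset, ap_iou: float) -> float:
    return evaluate_detections(
        [(detector.predict(rec), gts) for rec, gts in test_set], ap_iou
    )["ap"]


def run_experiment(
    seed: int = 0,
    config: PipelineConfig | None = None,
    source_config: SceneConfig | None = None,
    target_config: SceneConfig | None = None,
    n_source: int = 20,
    n_target_test: int = 25,
    n_video_frames: int = 480,
    video_drift_cycles: float = 6.0,
    search_space: SearchSpace | None = None,
) -> ExperimentResult:
    """Full desk-scale run on the synthetic top-view → tilted-view pair.

    Also trains a source-only baseline so the adaptation gain
    (self-trained minus source-only target AP) is measured within the run.
    """
    config = config or PipelineConfig()
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(5)
    ]
    if source_config is None:
        # source pens are recorded at a different resolution than the target
        source_config = SceneConfig(
            viewpoint="top", illumination="day", width=160, height=160
        )
    if target_config is None:
        target_config = SceneConfig(
            viewpoint="tilted", illumination="night", seed=seeds[1]
        )
    source, _, _ = generate_domain_pair(
        source_config, target_config, n_source, 1, 1, seed=seeds[0]
    )
    space = search_space or (
        SearchSpace.miniature(config.miniature_n_image_max)
        if config.miniature_n_image_max
        else SearchSpace()
    )

    # target video → key frames, SLOT, background
    video = list(generate_video(target_config, n_frames=n_video_frames,
                                rng=np.random.default_rng(seeds[1]),
                                drift_cycles=video_drift_cycles))
    # benchmark protocol: a held-out, evenly spaced subset of the target
    # video is annotated for testing; those frames never enter the
    # unlabeled self-training pool
    test_stride = max(n_video_frames // max(n_target_test, 1), 1)
    test_idx = set(range(test_stride // 2, n_video_frames, test_stride))
    target_test = LabeledDataset(
        [(ImageRecord(f"test_{rec.image_id}", rec.pixels), boxes)
         for i, (rec, boxes) in enumerate(video) if i in test_idx]
    )
    target = prepare_target(video, config, exclude_indices=test_idx)
    # adaptation-stage detectors subtract the pen's CMA background; the
    # source-only baseline has no target footage and estimates its own
    factory = _detector_factory(config, background=target.background)
    source_only_factory = _detector_factory(config)
    logger.info(
        "target video: %d frames → %d key frames, SLOT entropy %.4f",
        len(video), len(target.keyframe_indices),
        float(target.entropy.values[target.keyframe_indices].max()),
    )

    # copy-paste evaluation data
    patches = extract_objects(target.slot_record, target.slot_boxes, config.paste_mode)
    eval_set = build_eval_set(target.background, patches, config.paste_config(seeds[2]))

    # source-only baseline
    source_only = source_only_factory()
    source_only.train(source, max_epochs=config.base_epochs,
                      patience=config.early_stop_patience)
    source_only_ap = _test_ap(source_only, target_test, config.ap_iou)

    # augmentation search and base model
    slot_ds = LabeledDataset([(target.slot_record, target.slot_boxes)])
    ga = config.ga_config(seeds[3])
    best, das_log = run_das(
        space, ga, factory, source, slot_ds, eval_set, background=target.background
    )
    augmented = augment_slot(
        target.slot_record, target.slot_boxes, best,
        background=target.background, seed=ga.seed,
    )
    base = factory()
    base.train(
        LabeledDataset.concat(source, slot_ds, augmented),
        max_epochs=config.base_epochs,
        patience=config.early_stop_patience,
    )
    base_ap = _test_ap(base, target_test, config.ap_iou)

    # self-training on the unlabeled key frames
    final, st_log = self_train(
        base.clone_state(), source, slot_ds, target.unlabeled,
        config.selftrain_config(), test_set=target_test,
    )
    self_trained_ap = _test_ap(final, target_test, config.ap_iou)

    return ExperimentResult(
        source_only_ap=source_only_ap,
        base_ap=base_ap,
        self_trained_ap=self_trained_ap,
        best_chromosome=best,
        das_log=das_log,
        selftrain_log=st_log,
        n_keyframes=len(target.keyframe_indices),
        n_video_frames=len(video),
        slot_entropy=float(target.entropy.values[target.keyframe_indices].max()),
        n_test_images=len(target_test),
    )
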