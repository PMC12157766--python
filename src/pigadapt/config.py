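"""Single-document pipeline configuration.

One YAML file mirrors every stage default: the key-frame entropy
threshold, copy-paste evaluation-set size, GA budget (generations,
population, operator counts, fitness epochs, early-stop patience),
self-training schedule and confidence threshold, NMS/AP IoU thresholds,
and the global seed.  Validation happens at load time against every
module's constraints.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .copy_paste import PasteConfig
from .das import GAConfig
from .keyframe import KeyframeConfig
from .selftrain import SelfTrainConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # key-frame selection
    tau_ent: float = 0.05
    entropy_normalization: str = "bits_over_8"
    # copy-paste evaluation data
    eval_images: int = 100
    eval_objects_per_image: tuple[int, int] = (5, 30)
    eval_max_pairwise_iou: float = 0.3
    paste_mode: str = "polygon"
    # augmentation search
    generations: int = 3
    population_size: int = 20
    crossovers: int = 10
    mutations: int = 10
    fitness_epochs: int = 30
    early_stop_patience: int | None = 3
    miniature_n_image_max: int | None = 60
    # base-model training
    base_epochs: int = 30
    # self-training
    iterations: int = 5
    epochs_per_iteration: int = 5
    tau_conf: float = 0.01
    nms_iou: float = 0.5
    # evaluation
    ap_iou: float = 0.5
    # detector
    detector: str = "reference"
    detector_min_area: float = 30.0
    # global
    seed: int = 0

    def keyframe_config(self) -> KeyframeConfig:
        return KeyframeConfig(
            tau_ent=self.tau_ent, normalization=self.entropy_normalization
        )

    def paste_config(self, seed: int) -> PasteConfig:
        return PasteConfig(
            n_images=self.eval_images,
            objects_per_image=tuple(self.eval_objects_per_image),
            max_pairwise_iou=self.eval_max_pairwise_iou,
            mode=self.paste_mode,
            seed=seed,
        )

    def ga_config(self, seed: int) -> GAConfig:
        return GAConfig(
            generations=self.generations,
            population_size=self.population_size,
            crossovers=self.crossovers,
            mutations=self.mutations,
            fitness_epochs=self.fitness_epochs,
            patience=self.early_stop_patience,
            seed=seed,
        )

    def selftrain_config(self) -> SelfTrainConfig:
        return SelfTrainConfig(
            iterations=self.iterations,
            epochs_per_iteration=self.epochs_per_iteration,
            tau_conf=self.tau_conf,
            nms_iou=self.nms_iou,
        )

    def validate(self) -> None:
        self.keyframe_config()
        self.paste_config(0)
        self.ga_config(0)
        self.selftrain_config()
        if not 0.0 < self.ap_iou <= 1.0:
            raise ValueError("ap_iou must be in (0, 1]")
        if self.detector_min_area < 0:
            raise ValueError("detector_min_area must be nonnegative")


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "eval_objects_per_image" in doc:
        doc["eval_objects_per_image"] = tuple(doc["eval_objects_per_image"])
    config = PipelineConfig(**doc)
    config.validate()
    return config


def save_config(config: PipelineConfig, path: str | Path) -> None:
    doc = asdict(config)
    doc["eval_objects_per_image"] = list(doc["eval_objects_per_image"])
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
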