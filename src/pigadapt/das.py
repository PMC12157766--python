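"""Genetic-algorithm search over augmentation policies (DAS).

Each chromosome is an 8-gene augmentation policy; its fitness is the
11-point AP of a detector trained on source ∪ SLOT ∪ augmented-SLOT data
and evaluated on the copy-and-paste evaluation set.  Generations evolve
by keeping the top-K of everything evaluated so far (elitism via the
cumulative log), producing children by one-point crossover and
single-gene mutation, and re-evaluating; the best chromosome over the
whole log is the search result.

Defaults: 3 generations of population 20 built from 10 crossover plus 10
mutation children, fitness training up to 30 epochs with patience 3 —
60 fitness evaluations in total (1800 training epochs when early stopping
is disabled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .augment import GENE_NAMES, Chromosome, SearchSpace, augment_slot
from .boxes import ImageRecord, LabeledDataset, Box
from .detector import Detector
from .metrics import MatchResult, ap_11point, match_detections

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "FitnessRecord",
    "FitnessEvaluator",
    "init_population",
    "evaluate_fitness",
    "evolve_generation",
    "run_das",
    "count_search_space",
]


@dataclass
class GAConfig:
    """Search budget and operator counts."""

    generations: int = 3
    population_size: int = 20
    crossovers: int = 10
    mutations: int = 10
    fitness_epochs: int = 30
    patience: int | None = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if self.crossovers + self.mutations != self.population_size:
            raise ValueError(
                "crossovers + mutations must equal the population size "
                f"({self.crossovers}+{self.mutations} != {self.population_size})"
            )


@dataclass
class FitnessRecord:
    chromosome: Chromosome
    fitness: float
    generation: int
    epochs_trained: int
    valid: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fitness <= 1.0:
            raise ValueError("fitness must lie in [0, 1]")


def init_population(
    space: SearchSpace, k: int, rng: np.random.Generator
) -> list[Chromosome]:
    """K chromosomes drawn uniformly per gene, then constraint-repaired."""
    return [space.sample(rng) for _ in range(k)]


class FitnessEvaluator:
    """Trains a fresh detector per chromosome and caches results by genes.

    The cache is keyed by the full gene tuple: the GA revisits chromosomes
    and detector training is the cost center, so a revisit returns the
    stored record without any training.
    """

    def __init__(
        self,
        detector_factory: Callable[[], Detector],
        source: LabeledDataset,
        slot: LabeledDataset,
        eval_set: LabeledDataset,
        ga_config: GAConfig,
        background: np.ndarray | None = None,
        iou_threshold: float = 0.5,
    ):
        overlap = set(eval_set.image_ids()) & (
            set(source.image_ids()) | set(slot.image_ids())
        )
        if overlap:
            raise ValueError(f"eval set overlaps training images: {sorted(overlap)[:3]}")
        self.detector_factory = detector_factory
        self.source = source
        self.slot = slot
        self.eval_set = eval_set
        self.ga_config = ga_config
        self.background = background
        self.iou_threshold = iou_threshold
        self.cache: dict[tuple, FitnessRecord] = {}
        self.trainings = 0  # number of actual (non-cached) trainings

    def _eval_ap(self, detector: Detector) -> float:
        results: list[MatchResult] = []
        for record, gts in self.eval_set:
            preds = detector.predict(record)
            results.append(match_detections(preds, gts, self.iou_threshold))
        merged = MatchResult.merge(results)
        return ap_11point(merged) if merged.n_ground_truth else 0.0

    def evaluate(self, chromosome: Chromosome, generation: int = 0) -> FitnessRecord:
        key = chromosome.genes()
        if key in self.cache:
            return self.cache[key]
        slot_record, slot_boxes = self.slot.records[0]
        try:
            augmented = augment_slot(
                slot_record,
                slot_boxes,
                chromosome,
                background=self.background,
                seed=self.ga_config.seed,
            )
            train_set = LabeledDataset.concat(self.source, self.slot, augmented)
            detector = self.detector_factory()
            log = detector.train(
                train_set,
                max_epochs=self.ga_config.fitness_epochs,
                patience=self.ga_config.patience,
            )
            record = FitnessRecord(
                chromosome=chromosome,
                fitness=self._eval_ap(detector),
                generation=generation,
                epochs_trained=log.epochs_trained,
            )
        except Exception:  # noqa: BLE001 - a failed training scores 0, logged
            logger.exception("fitness evaluation failed for %s", chromosome)
            record = FitnessRecord(
                chromosome=chromosome,
                fitness=0.0,
                generation=generation,
                epochs_trained=0,
                valid=False,
            )
        self.cache[key] = record
        self.trainings += 1
        return record


def evaluate_fitness(
    chromosome: Chromosome,
    detector_factory: Callable[[], Detector],
    source: LabeledDataset,
    slot: LabeledDataset,
    eval_set: LabeledDataset,
    ga_config: GAConfig | None = None,
) -> FitnessRecord:
    """One-off fitness evaluation (no shared cache); see FitnessEvaluator."""
    evaluator = FitnessEvaluator(
        detector_factory, source, slot, eval_set, ga_config or GAConfig()
    )
    return evaluator.evaluate(chromosome)


def _crossover(
    a: Chromosome, b: Chromosome, rng: np.random.Generator, space: SearchSpace
) -> Chromosome:
    """One-point crossover at a uniform internal gene boundary (1..7)."""
    cut = int(rng.integers(1, len(GENE_NAMES)))
    genes = a.genes()[:cut] + b.genes()[cut:]
    return space.repair(Chromosome.from_genes(genes))


def _mutate(
    parent: Chromosome, rng: np.random.Generator, space: SearchSpace
) -> Chromosome:
    """Resample exactly one uniformly chosen gene from its grid."""
    gene = GENE_NAMES[int(rng.integers(len(GENE_NAMES)))]
    grid = space.grid(gene)
    value = grid[int(rng.integers(len(grid)))]
    return space.repair(replace(parent, **{gene: value}))


def evolve_generation(
    scored: Sequence[FitnessRecord],
    ga_config: GAConfig,
    rng: np.random.Generator,
    space: SearchSpace | None = None,
) -> list[Chromosome]:
    """Next population: children of the top-K of everything scored so far.

    Elite selection is top-K by fitness with ties broken by evaluation
    order; children are ``crossovers`` one-point crossovers of uniformly
    drawn elite parent pairs plus ``mutations`` single-gene mutants of
    uniformly drawn elite members, all constraint-repaired.
    """
    if len(scored) < ga_config.population_size:
        raise ValueError("need at least population_size scored records")
    space = space or SearchSpace()
    order = sorted(range(len(scored)), key=lambda i: (-scored[i].fitness, i))
    elite = [scored[i].chromosome for i in order[: ga_config.population_size]]
    children: list[Chromosome] = []
    for _ in range(ga_config.crossovers):
        i, j = rng.integers(len(elite)), rng.integers(len(elite))
        children.append(_crossover(elite[int(i)], elite[int(j)], rng, space))
    for _ in range(ga_config.mutations):
        parent = elite[int(rng.integers(len(elite)))]
        children.append(_mutate(parent, rng, space))
    return children


def run_das(
    space: SearchSpace,
    ga_config: GAConfig,
    detector_factory: Callable[[], Detector],
    source: LabeledDataset,
    slot: LabeledDataset,
    eval_set: LabeledDataset,
    background: np.ndarray | None = None,
    evaluator: FitnessEvaluator | None = None,
) -> tuple[Chromosome, list[FitnessRecord]]:
    """Full search: G generations of K chromosomes, argmax over the log.

    The initial random population is evaluated as generation 1; later
    generations are the 10+10 children of the cumulative elite.  Returns
    (best chromosome, complete fitness log in evaluation order).
    """
    rng = np.random.default_rng(ga_config.seed)
    if evaluator is None:
        evaluator = FitnessEvaluator(
            detector_factory, source, slot, eval_set, ga_config, background=background
        )
    log: list[FitnessRecord] = []
    population = init_population(space, ga_config.population_size, rng)
    for generation in range(1, ga_config.generations + 1):
        for chromosome in population:
            record = evaluator.evaluate(chromosome, generation)
            log.append(
                replace_generation(record, generation)
                if record.generation != generation
                else record
            )
        if generation < ga_config.generations:
            population = evolve_generation(log, ga_config, rng, space)
    best = max(range(len(log)), key=lambda i: (log[i].fitness, -i))
    return log[best].chromosome, log


def replace_generation(record: FitnessRecord, generation: int) -> FitnessRecord:
    """Cached records keep their fitness but log under the current generation."""
    return FitnessRecord(
        chromosome=record.chromosome,
        fitness=record.fitness,
        generation=generation,
        epochs_trained=record.epochs_trained,
        valid=record.valid,
    )


def count_search_space(space: SearchSpace) -> int:
    """Exact number of distinct valid chromosomes in a search space.

    The flag-conditional fixings collapse genes: flag 0 contributes a
    single (p_trans, m_trans) combination, flips contribute |p_trans|
    each, and the four magnitude-bearing flags contribute
    |p_trans|·|m_trans| each.
    """
    n = len(space.n_image_values)
    p_in = len(space.p_zoom_in_values)
    m_in = len(space.m_zoom_in_values)
    p_out = len(space.p_zoom_out_values)
    m_out = len(space.m_zoom_out_values)
    p_t = len(space.p_trans_values)
    m_t = len(space.m_trans_values)
    flag_combos = 0
    for flag in space.f_trans_values:
        if flag == 0:
            flag_combos += 1
        elif flag in (5, 6):
            flag_combos += p_t
        else:
            flag_combos += p_t * m_t
    return n * p_in * m_in * p_out * m_out * flag_combos
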