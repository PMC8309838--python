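"""Genetic algorithm over binary feature subsets (wrapper selection).

Each individual is a bit vector over the feature columns; active bits are
the columns the classifier sees.  Fitness is the cross-validated AUC of a
model from the previously selected bucket restricted to the active columns;
ranking prefers, at equal AUC, the individual with *fewer* active features,
then the earlier-discovered one — the search looks for the smallest subset
that classifies best.

The generation skeleton mirrors the model-selection GA with its own quotas
(defaults: 20 elitist copies, 40 single-cutoff crossover children, 6
mutants, 74 random genomes — 140 individuals over 100 generations), the
same stagnation-triggered decimation, and an audited one-training-per-
individual budget in the default ``top_model`` fitness mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evaluation import Dataset, Evaluator
from .ga_models import STAGNATION_TOL, RankedModel

DEFAULT_FS_QUOTAS = {
    "selection": 20,
    "crossover": 40,
    "mutation": 6,
    "random": 74,
}

FITNESS_MODES = ("top_model", "model_set_max")


@dataclass(frozen=True)
class FSConfig:
    """Configuration of the feature-selection genetic algorithm."""

    population_size: int = 140
    generations: int = 100
    quotas: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FS_QUOTAS)
    )
    min_active: int = 1
    perturbation_patience: int = 10
    fitness_mode: str = "top_model"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.generations <= 0:
            raise ValueError("population_size and generations must be positive")
        if set(self.quotas) != set(DEFAULT_FS_QUOTAS):
            raise ValueError(
                f"quotas must name exactly {sorted(DEFAULT_FS_QUOTAS)}"
            )
        if any(q < 0 for q in self.quotas.values()):
            raise ValueError("quotas must be non-negative")
        if sum(self.quotas.values()) != self.population_size:
            raise ValueError(
                f"quota sum {sum(self.quotas.values())} != "
                f"population_size {self.population_size}"
            )
        if self.min_active < 1:
            raise ValueError("min_active must be >= 1")
        if self.fitness_mode not in FITNESS_MODES:
            raise ValueError(f"fitness_mode must be one of {FITNESS_MODES}")
        if self.perturbation_patience <= 0:
            raise ValueError("perturbation_patience must be positive")


def _repair(bits: np.ndarray, min_active: int, rng: np.random.Generator) -> np.ndarray:
    """Activate random inactive bits until the floor is met."""
    short = min_active - int(bits.sum())
    if short > 0:
        off = np.flatnonzero(~bits)
        bits = bits.copy()
        bits[rng.choice(off, size=short, replace=False)] = True
    return bits


def random_bit_genome(
    length: int, min_active: int, rng: np.random.Generator
) -> np.ndarray:
    """Each bit active with probability 1/2, then repaired to the floor."""
    bits = rng.random(length) < 0.5
    return _repair(bits, min_active, rng)


def crossover_bits(
    p1: np.ndarray,
    p2: np.ndarray,
    cutoff: int,
    min_active: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Single-cutoff crossover of two bit genomes.

    Child 1 takes the first ``cutoff`` bits of parent 1 and the rest of
    parent 2; child 2 is the mirror image.  A child falling below
    ``min_active`` is repaired by activating random bits.
    """
    p1 = np.asarray(p1, dtype=bool)
    p2 = np.asarray(p2, dtype=bool)
    if p1.shape != p2.shape:
        raise ValueError("parent genomes differ in length")
    n = p1.size
    if not 0 < cutoff < n:
        raise ValueError(f"cutoff must be in (0, {n}), got {cutoff}")
    if rng is None:
        rng = np.random.default_rng(0)
    d1 = np.concatenate([p1[:cutoff], p2[cutoff:]])
    d2 = np.concatenate([p2[:cutoff], p1[cutoff:]])
    return _repair(d1, min_active, rng), _repair(d2, min_active, rng)


def mutate_bit(
    genome: np.ndarray, rng: np.random.Generator, min_active: int = 1
) -> np.ndarray:
    """Flip exactly one bit, never violating the active-bit floor.

    When the genome sits exactly at the floor, only activations (or flips
    of inactive bits) are candidates.
    """
    bits = np.asarray(genome, dtype=bool).copy()
    n_active = int(bits.sum())
    if n_active > min_active:
        candidates = np.arange(bits.size)
    else:
        candidates = np.flatnonzero(~bits)
    if candidates.size == 0:
        raise ValueError("no legal bit flip exists")
    pos = int(rng.choice(candidates))
    bits[pos] = ~bits[pos]
    return bits


@dataclass(frozen=True)
class RankedSubset:
    """A feature subset with its score, used for ranking and reporting."""

    bits: np.ndarray
    score: float
    n_active: int
    model: RankedModel
    discovery: int

    def sort_key(self) -> tuple:
        # higher score first, then fewer active bits, then earlier discovery
        return (-self.score, self.n_active, self.discovery)


def subset_fitness(
    bits: np.ndarray,
    models: Sequence[RankedModel],
    evaluator: Evaluator,
    fitness_mode: str = "top_model",
) -> Tuple[float, RankedModel, int]:
    """Score one bit genome against the bucket of models.

    ``top_model`` trains only the bucket's rank-1 model (one training per
    individual); ``model_set_max`` trains every model in the bucket and
    keeps the maximum.  Returns (score, scoring model, trainings spent).
    """
    if len(models) == 0:
        raise ValueError("empty model bucket")
    if not np.any(bits):
        return 0.0, models[0], 0
    if fitness_mode == "top_model":
        return evaluator.fitness(models[0].config, bits), models[0], 1
    best_score, best_model = -np.inf, models[0]
    for rm in models:
        s = evaluator.fitness(rm.config, bits)
        if s > best_score:
            best_score, best_model = s, rm
    return best_score, best_model, len(models)


def _next_generation_bits(
    ranked: List[RankedSubset],
    cfg: FSConfig,
    length: int,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    q = cfg.quotas
    n = len(ranked)
    new: List[np.ndarray] = []

    new.extend(ranked[i].bits for i in range(q["selection"]))

    elites = ranked[: max(q["selection"], 1)]
    children: List[np.ndarray] = []
    while len(children) < q["crossover"]:
        p1 = elites[int(rng.integers(0, len(elites)))].bits
        p2 = elites[int(rng.integers(0, len(elites)))].bits
        cutoff = int(rng.integers(1, length))
        c1, c2 = crossover_bits(p1, p2, cutoff, cfg.min_active, rng)
        children.extend([c1, c2])
    new.extend(children[: q["crossover"]])

    # mutation placement: one among the best three, one among the worst
    # three, the rest anywhere in the population
    sources: List[np.ndarray] = []
    if q["mutation"] > 0:
        head = min(3, n)
        sources.append(ranked[int(rng.integers(0, head))].bits)
        if q["mutation"] > 1:
            sources.append(ranked[n - head + int(rng.integers(0, head))].bits)
        while len(sources) < q["mutation"]:
            sources.append(ranked[int(rng.integers(0, n))].bits)
    new.extend(mutate_bit(b, rng, cfg.min_active) for b in sources)

    new.extend(
        random_bit_genome(length, cfg.min_active, rng)
        for _ in range(q["random"])
    )
    assert len(new) == cfg.population_size
    return new


def run_feature_selection(
    data: Dataset,
    models: Sequence[RankedModel],
    cfg: Optional[FSConfig] = None,
    evaluator: Optional[Evaluator] = None,
    log: Optional[list] = None,
) -> Tuple[RankedSubset, dict]:
    """Evolve feature subsets scored by the bucket of models.

    Returns the best subset ever seen (highest score, then fewest active
    features, then earliest discovery) together with an audit of the
    training budget: in ``top_model`` mode exactly
    ``population_size * generations`` models are trained.
    """
    cfg = cfg or FSConfig()
    if len(models) == 0:
        raise ValueError("empty model bucket")
    ev = evaluator or Evaluator(data, cfg.seed)
    length = data.d
    if cfg.min_active > length:
        raise ValueError("min_active exceeds the number of feature columns")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))

    population = [
        random_bit_genome(length, cfg.min_active, rng)
        for _ in range(cfg.population_size)
    ]
    trained = 0
    best_history: List[float] = []
    perturbations = 0
    flat_run = 0
    prev_best: Optional[RankedSubset] = None
    discovery = 0
    best_ever: Optional[RankedSubset] = None

    for gen in range(cfg.generations):
        scored: List[RankedSubset] = []
        for bits in population:
            score, model, cost = subset_fitness(bits, models, ev, cfg.fitness_mode)
            trained += cost
            scored.append(
                RankedSubset(
                    bits=bits,
                    score=score,
                    n_active=int(bits.sum()),
                    model=model,
                    discovery=discovery,
                )
            )
            discovery += 1
        ranked = sorted(scored, key=RankedSubset.sort_key)
        gen_best = ranked[0]
        if best_ever is None or gen_best.sort_key() < best_ever.sort_key():
            best_ever = gen_best
        improved = prev_best is None or best_ever.sort_key() < prev_best.sort_key()
        flat_run = 1 if improved else flat_run + 1
        prev_best = best_ever
        best_history.append(best_ever.score)
        if log is not None:
            log.append(
                {
                    "stage": "feature_selection",
                    "generation": gen,
                    "best_score": gen_best.score,
                    "best_n_active": gen_best.n_active,
                    "best_so_far": best_ever.score,
                    "median_score": float(np.median([s.score for s in scored])),
                }
            )
        if gen == cfg.generations - 1:
            break
        if flat_run >= cfg.perturbation_patience:
            population = [ranked[0].bits] + [
                random_bit_genome(length, cfg.min_active, rng)
                for _ in range(cfg.population_size - 1)
            ]
            perturbations += 1
            flat_run = 0
        else:
            population = _next_generation_bits(ranked, cfg, length, rng)

    audit = {
        "trained_models": trained,
        "population_size": cfg.population_size,
        "generations": cfg.generations,
        "strategy_quotas": dict(cfg.quotas),
        "perturbations": perturbations,
        "fitness_mode": cfg.fitness_mode,
        "best_score": best_ever.score,
        "best_n_active": best_ever.n_active,
        "best_score_history": best_history,
        "seed": cfg.seed,
    }
    return best_ever, audit
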