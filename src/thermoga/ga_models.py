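"""Genetic algorithm over SVM configurations (the "Bucket of Models").

Each individual is a genome of six indices into the parameter lists.  Every
generation is rebuilt from five reproduction strategies with fixed quotas
(defaults from the study configuration: 10 elitist copies, 40 crossover
children, 20 asexual ±1 variants, 10 mutants, 60 random genomes — 140 in
total, evolved for 30 generations).  Every individual of every generation
is evaluated, so the audited number of trained models is exactly
``population_size x generations``.

After prolonged stagnation of the best fitness a *decimation* event fires:
only the strongest individual survives and the rest of the population is
regenerated at random.

The search returns the ten best distinct canonical configurations observed
anywhere in the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evaluation import Dataset, Evaluator
from .params import (
    PARAM_ORDER,
    ModelConfig,
    ParameterSpace,
    build_parameter_space,
    decode,
    validate_genome,
)

STAGNATION_TOL = 1e-9

DEFAULT_MODEL_QUOTAS = {
    "selection": 10,
    "crossover": 40,
    "asexual": 20,
    "mutation": 10,
    "random": 60,
}


@dataclass(frozen=True)
class GAConfig:
    """Configuration of the model-selection genetic algorithm."""

    population_size: int = 140
    generations: int = 30
    quotas: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MODEL_QUOTAS)
    )
    perturbation_patience: int = 10
    # Off by default: the audited budget assumes one training per
    # individual per generation; caching reuses the fitness of a canonical
    # configuration seen before and counts only actual trainings.
    cache_fitness: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.generations <= 0:
            raise ValueError("population_size and generations must be positive")
        if set(self.quotas) != set(DEFAULT_MODEL_QUOTAS):
            raise ValueError(
                f"quotas must name exactly {sorted(DEFAULT_MODEL_QUOTAS)}"
            )
        if any(q < 0 for q in self.quotas.values()):
            raise ValueError("quotas must be non-negative")
        if sum(self.quotas.values()) != self.population_size:
            raise ValueError(
                f"quota sum {sum(self.quotas.values())} != "
                f"population_size {self.population_size}"
            )
        if self.perturbation_patience <= 0:
            raise ValueError("perturbation_patience must be positive")


@dataclass(frozen=True)
class RankedModel:
    """One entry of the returned bucket: a configuration and its fitness."""

    config: ModelConfig
    fitness: float
    genome: tuple


def random_genome(space: ParameterSpace, rng: np.random.Generator) -> tuple:
    return tuple(
        int(rng.integers(0, len(space.values_of(p)))) for p in PARAM_ORDER
    )


def init_population(
    n: int, space: ParameterSpace, rng: np.random.Generator
) -> List[tuple]:
    """``n`` uniformly random valid genomes."""
    if n <= 0:
        raise ValueError("population size must be positive")
    return [random_genome(space, rng) for _ in range(n)]


def crossover(
    p1: Sequence[int], p2: Sequence[int], rng: np.random.Generator
) -> Tuple[tuple, tuple]:
    """Balanced uniform crossover: each child takes 3 genes per parent.

    The positions inherited from parent 1 by child 1 are drawn at random;
    child 2 takes the complementary assignment.
    """
    n = len(p1)
    take = np.zeros(n, dtype=bool)
    take[rng.choice(n, size=n // 2, replace=False)] = True
    c1 = tuple(p1[i] if take[i] else p2[i] for i in range(n))
    c2 = tuple(p2[i] if take[i] else p1[i] for i in range(n))
    return c1, c2


def asexual_variants(
    parents: Sequence[tuple],
    quota: int,
    space: ParameterSpace,
    rng: Optional[np.random.Generator] = None,
) -> List[tuple]:
    """±1 index variants ("fine tuning") of the top-ranked parents.

    Genes are visited in fixed order; for each, the index−1 and index+1
    variants are emitted (out-of-bounds neighbors skipped, not wrapped —
    the lists are ordered scales).  Parents are consumed in rank order
    until the quota is filled; if every parent is exhausted the remainder
    is filled with random genomes.
    """
    out: List[tuple] = []
    if quota <= 0:
        return out
    for parent in parents:
        for pos, name in enumerate(PARAM_ORDER):
            limit = len(space.values_of(name))
            for delta in (-1, +1):
                idx = parent[pos] + delta
                if 0 <= idx < limit:
                    variant = list(parent)
                    variant[pos] = idx
                    out.append(tuple(variant))
                    if len(out) == quota:
                        return out
    if rng is None:
        rng = np.random.default_rng(0)
    while len(out) < quota:
        out.append(random_genome(space, rng))
    return out


def mutate(
    genome: Sequence[int], space: ParameterSpace, rng: np.random.Generator
) -> tuple:
    """Change exactly one gene to a different admissible value.

    Genes whose list holds a single value cannot change and are excluded
    from the draw; the result is always at Hamming distance 1.
    """
    mutable = [
        i for i, p in enumerate(PARAM_ORDER) if len(space.values_of(p)) > 1
    ]
    if not mutable:
        raise ValueError("no mutable gene: every parameter list has length 1")
    pos = int(rng.choice(mutable))
    limit = len(space.values_of(PARAM_ORDER[pos]))
    new = int(rng.integers(0, limit - 1))
    if new >= genome[pos]:
        new += 1  # skip the current value
    child = list(genome)
    child[pos] = new
    return tuple(child)


def next_generation(
    ranked: Sequence[tuple],
    cfg: GAConfig,
    space: ParameterSpace,
    rng: np.random.Generator,
) -> Tuple[List[tuple], Dict[str, int]]:
    """Build the next population from a ranked (best-first) one.

    Strategy order is fixed: elitist copies, crossover children of elite
    pairs, asexual ±1 variants, mutants (one from the top three, one from
    the bottom three, the rest from anywhere), random genomes.
    """
    q = cfg.quotas
    n = len(ranked)
    if n != cfg.population_size:
        raise ValueError("ranked population size != cfg.population_size")
    elites = list(ranked[: max(q["selection"], 1)])
    new: List[tuple] = []
    counts: Dict[str, int] = {}

    new.extend(ranked[: q["selection"]])
    counts["selection"] = q["selection"]

    children: List[tuple] = []
    while len(children) < q["crossover"]:
        p1 = elites[int(rng.integers(0, len(elites)))]
        p2 = elites[int(rng.integers(0, len(elites)))]
        c1, c2 = crossover(p1, p2, rng)
        children.extend([c1, c2])
    new.extend(children[: q["crossover"]])
    counts["crossover"] = q["crossover"]

    new.extend(asexual_variants(ranked, q["asexual"], space, rng))
    counts["asexual"] = q["asexual"]

    mut_sources: List[tuple] = []
    if q["mutation"] > 0:
        head = min(3, n)
        tail = min(3, n)
        mut_sources.append(ranked[int(rng.integers(0, head))])
        if q["mutation"] > 1:
            mut_sources.append(ranked[n - tail + int(rng.integers(0, tail))])
        while len(mut_sources) < q["mutation"]:
            mut_sources.append(ranked[int(rng.integers(0, n))])
    new.extend(mutate(g, space, rng) for g in mut_sources)
    counts["mutation"] = q["mutation"]

    new.extend(random_genome(space, rng) for _ in range(q["random"]))
    counts["random"] = q["random"]

    assert len(new) == cfg.population_size
    return new, counts


def check_perturbation(history: Sequence[float], cfg: GAConfig) -> bool:
    """True when the best fitness has been flat for ``patience`` generations.

    ``history`` is the per-generation best-fitness series; the trigger fires
    when the trailing ``perturbation_patience`` entries agree within 1e-9.
    """
    if len(history) == 0:
        raise ValueError("empty fitness history")
    p = cfg.perturbation_patience
    if len(history) < p:
        return False
    tail = np.asarray(history[-p:], dtype=float)
    return bool(tail.max() - tail.min() <= STAGNATION_TOL)


def apply_decimation(
    ranked: Sequence[tuple],
    cfg: GAConfig,
    space: ParameterSpace,
    rng: np.random.Generator,
) -> List[tuple]:
    """Keep only the strongest individual; regenerate the rest at random."""
    return [ranked[0]] + init_population(cfg.population_size - 1, space, rng)


def _stable_rank(population: List[tuple], fits: List[float]) -> List[int]:
    # best-first, ties broken by current position (stable)
    return sorted(range(len(population)), key=lambda i: (-fits[i], i))


def run_model_selection(
    data: Dataset,
    cfg: Optional[GAConfig] = None,
    space: Optional[ParameterSpace] = None,
    evaluator: Optional[Evaluator] = None,
    n_best: int = 10,
    log: Optional[list] = None,
) -> Tuple[List[RankedModel], dict]:
    """Evolve SVM configurations and return the bucket of best models.

    Every individual of every generation is evaluated (no fitness caching),
    so ``audit["trained_models"] == population_size * generations``.  The
    returned bucket holds the ``n_best`` best *distinct canonical*
    configurations seen anywhere in the run, best-first, ties broken by
    earlier discovery.
    """
    cfg = cfg or GAConfig()
    space = space or build_parameter_space()
    ev = evaluator or Evaluator(data, cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))

    population = init_population(cfg.population_size, space, rng)
    trained = 0
    best_history: List[float] = []
    perturbations = 0
    flat_run = 0
    prev_best_so_far: Optional[float] = None
    seen: Dict[tuple, RankedModel] = {}
    discovery: Dict[tuple, int] = {}
    n_seen = 0

    cache: Dict[tuple, float] = {}
    for gen in range(cfg.generations):
        fits = []
        for g in population:
            config = decode(g, space)
            if cfg.cache_fitness:
                canon = config.canonical(space)
                if canon not in cache:
                    cache[canon] = ev.fitness(config)
                    trained += 1
                fits.append(cache[canon])
            else:
                fits.append(ev.fitness(config))
                trained += 1
        for g, f in zip(population, fits):
            config = decode(g, space)
            canon = config.canonical(space)
            if canon not in seen:
                seen[canon] = RankedModel(config=config, fitness=f, genome=g)
                discovery[canon] = n_seen
                n_seen += 1
            elif f > seen[canon].fitness:
                seen[canon] = RankedModel(
                    config=seen[canon].config, fitness=f, genome=seen[canon].genome
                )
        order = _stable_rank(population, fits)
        ranked = [population[i] for i in order]
        best = fits[order[0]]
        best_so_far = best if prev_best_so_far is None else max(prev_best_so_far, best)
        if prev_best_so_far is not None and (
            best_so_far - prev_best_so_far <= STAGNATION_TOL
        ):
            flat_run += 1
        else:
            flat_run = 1
        prev_best_so_far = best_so_far
        best_history.append(best_so_far)
        if log is not None:
            log.append(
                {
                    "stage": "model_selection",
                    "generation": gen,
                    "best_fitness": best,
                    "best_so_far": best_so_far,
                    "median_fitness": float(np.median(fits)),
                }
            )
        if gen == cfg.generations - 1:
            break
        if flat_run >= cfg.perturbation_patience:
            population = apply_decimation(ranked, cfg, space, rng)
            perturbations += 1
            flat_run = 0
        else:
            population, _ = next_generation(ranked, cfg, space, rng)

    top = sorted(
        seen.values(),
        key=lambda rm: (-rm.fitness, discovery[rm.config.canonical(space)]),
    )[:n_best]
    audit = {
        "trained_models": trained,
        "population_size": cfg.population_size,
        "generations": cfg.generations,
        "strategy_quotas": dict(cfg.quotas),
        "perturbations": perturbations,
        "best_fitness": best_history[-1],
        "best_fitness_history": best_history,
        "distinct_configs_seen": len(seen),
        "seed": cfg.seed,
    }
    return top, audit
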