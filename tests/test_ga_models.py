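"""Model-selection GA: operators, generation contract, stagnation restart."""

import numpy as np
import pytest
from scipy.stats import chisquare

import thermoga as tg
from thermoga.ga_models import (
    GAConfig,
    apply_decimation,
    asexual_variants,
    check_perturbation,
    crossover,
    init_population,
    mutate,
    next_generation,
    run_model_selection,
)
from thermoga.params import PARAM_ORDER, validate_genome


def rng(seed=0):
    return np.random.default_rng(seed)


def test_init_population_seeded_and_valid(space):
    p1 = init_population(140, space, rng(1))
    p2 = init_population(140, space, rng(1))
    assert p1 == p2
    for g in p1:
        validate_genome(g, space)


def test_init_population_kernel_gene_uniform(space):
    pop = init_population(1000, space, rng(2))
    kernel_idx = [g[5] for g in pop]
    counts = np.bincount(kernel_idx, minlength=3)
    assert chisquare(counts).pvalue > 0.01


def test_crossover_balanced_split(space):
    p1 = (0, 0, 0, 0, 0, 0)
    p2 = tuple(len(space.values_of(p)) - 1 for p in PARAM_ORDER)
    for seed in range(20):
        c1, c2 = crossover(p1, p2, rng(seed))
        assert sum(v == 0 for v in c1) == 3
        assert sum(v == 0 for v in c2) == 3
        # children are complementary
        assert all((a == 0) != (b == 0) for a, b in zip(c1, c2))


def test_crossover_identical_parents_identity(space):
    g = (3, 10, 20, 2, 1, 1)
    c1, c2 = crossover(g, g, rng(0))
    assert c1 == g and c2 == g


def test_crossover_genes_come_from_parents(space):
    r = rng(7)
    for _ in range(50):
        p1 = tuple(int(r.integers(0, len(space.values_of(p)))) for p in PARAM_ORDER)
        p2 = tuple(int(r.integers(0, len(space.values_of(p)))) for p in PARAM_ORDER)
        for child in crossover(p1, p2, r):
            assert all(c in (a, b) for c, a, b in zip(child, p1, p2))


def test_asexual_variants_plus_minus_one(space):
    parent = (3, 5, 10, 2, 1, 1)
    variants = asexual_variants([parent], 12, space)
    # gamma (position 1) at index 5 -> variants at 4 and 6 with rest unchanged
    gamma_variants = [v for v in variants if v[1] != 5]
    assert (3, 4, 10, 2, 1, 1) in gamma_variants
    assert (3, 6, 10, 2, 1, 1) in gamma_variants
    for v in variants:
        diffs = [abs(a - b) for a, b in zip(v, parent)]
        assert sum(d != 0 for d in diffs) == 1 and max(diffs) == 1


def test_asexual_variants_skip_out_of_bounds(space):
    parent = (0, 0, 0, 0, 0, 0)  # every gene at the lower boundary
    variants = asexual_variants([parent], 6, space)
    for v in variants:
        validate_genome(v, space)
        assert sum(a != b for a, b in zip(v, parent)) == 1
        # only +1 variants exist at the boundary
        assert all(x >= 0 for x in v)
    assert len(variants) == 6


def test_asexual_variants_continue_with_next_parent(space):
    # a fully interior parent yields 12 variants; quota 20 must consume
    # the second-ranked parent too
    interior = (3, 5, 10, 2, 1, 1)
    second = (4, 6, 11, 3, 2, 2)
    variants = asexual_variants([interior, second], 20, space)
    assert len(variants) == 20
    from_second = [v for v in variants if sum(a != b for a, b in zip(v, second)) == 1]
    assert len(from_second) == 8


def test_mutate_hamming_distance_one(space):
    r = rng(3)
    for _ in range(100):
        g = tuple(int(r.integers(0, len(space.values_of(p)))) for p in PARAM_ORDER)
        m = mutate(g, space, r)
        validate_genome(m, space)
        assert sum(a != b for a, b in zip(g, m)) == 1


def test_mutate_skips_single_value_lists():
    space = tg.ParameterSpace(
        tolerance=(0.1,), gamma=(0.1, 0.2), coef0=(0.0,), nu=(0.5,),
        degree=(2,), kernel=("rbf", "poly", "sigmoid"),
    )
    r = rng(0)
    for _ in range(50):
        m = mutate((0, 0, 0, 0, 0, 0), space, r)
        assert m[0] == 0 and m[2] == 0 and m[3] == 0 and m[4] == 0
        assert m[1] != 0 or m[5] != 0


def test_mutated_position_roughly_uniform(space):
    r = rng(11)
    g = (3, 5, 10, 2, 1, 1)
    positions = []
    for _ in range(1000):
        m = mutate(g, space, r)
        positions.append(next(i for i in range(6) if m[i] != g[i]))
    counts = np.bincount(positions, minlength=6)
    assert chisquare(counts).pvalue > 0.01


def test_next_generation_quota_contract(space):
    cfg = GAConfig(seed=0)
    r = rng(5)
    ranked = init_population(140, space, r)
    new, counts = next_generation(ranked, cfg, space, r)
    assert len(new) == 140
    assert counts == {"selection": 10, "crossover": 40, "asexual": 20,
                      "mutation": 10, "random": 60}
    # elites survive verbatim at the head of the new population
    assert new[:10] == ranked[:10]
    for g in new:
        validate_genome(g, space)


def test_next_generation_deterministic(space):
    cfg = GAConfig(seed=0)
    ranked = init_population(140, space, rng(5))
    n1, _ = next_generation(ranked, cfg, space, rng(9))
    n2, _ = next_generation(ranked, cfg, space, rng(9))
    assert n1 == n2


def test_quota_sum_mismatch_rejected():
    with pytest.raises(ValueError, match="quota sum"):
        GAConfig(population_size=140,
                 quotas={"selection": 10, "crossover": 40, "asexual": 20,
                         "mutation": 10, "random": 59})


def test_perturbation_trigger_rules():
    cfg = GAConfig(perturbation_patience=10, seed=0)
    assert check_perturbation([0.8] * 10, cfg)
    assert not check_perturbation([0.8] * 9, cfg)
    assert not check_perturbation(list(np.linspace(0.5, 0.9, 30)), cfg)
    with pytest.raises(ValueError, match="empty"):
        check_perturbation([], cfg)


def test_decimation_keeps_only_the_strongest(space):
    cfg = GAConfig(seed=0)
    ranked = init_population(140, space, rng(1))
    new = apply_decimation(ranked, cfg, space, rng(2))
    assert len(new) == 140
    assert new[0] == ranked[0]
    # the remainder is regenerated, not copied wholesale
    assert new[1:] != ranked[1:]


def test_run_counts_trainings_exactly(small_table, tiny_ga_cfg, space):
    cfg = GAConfig(population_size=2, generations=2,
                   quotas={"selection": 1, "crossover": 0, "asexual": 0,
                           "mutation": 1, "random": 0}, seed=0)
    _, audit = run_model_selection(small_table, cfg, space)
    assert audit["trained_models"] == 4

    top, audit = run_model_selection(small_table, tiny_ga_cfg, space)
    assert audit["trained_models"] == 14 * 3
    assert len(top) == 10
    # distinct canonical forms
    canons = [rm.config.canonical(space) for rm in top]
    assert len(set(canons)) == len(canons)


def test_fitness_caching_reduces_trainings_only(small_table, tiny_ga_cfg, space):
    import dataclasses

    cached_cfg = dataclasses.replace(tiny_ga_cfg, cache_fitness=True)
    top_c, audit_c = run_model_selection(small_table, cached_cfg, space)
    top_p, audit_p = run_model_selection(small_table, tiny_ga_cfg, space)
    # elites are re-encountered every generation, so caching trains fewer
    assert audit_c["trained_models"] < audit_p["trained_models"]
    # fitness is deterministic per canonical config: same search trajectory
    assert audit_c["best_fitness_history"] == audit_p["best_fitness_history"]
    assert [rm.config for rm in top_c] == [rm.config for rm in top_p]


def test_best_so_far_monotone_and_reproducible(small_table, tiny_ga_cfg, space):
    top1, audit1 = run_model_selection(small_table, tiny_ga_cfg, space)
    top2, audit2 = run_model_selection(small_table, tiny_ga_cfg, space)
    hist = audit1["best_fitness_history"]
    assert all(b >= a for a, b in zip(hist, hist[1:]))
    assert audit1["best_fitness_history"] == audit2["best_fitness_history"]
    assert [rm.config for rm in top1] == [rm.config for rm in top2]
    assert [rm.fitness for rm in top1] == [rm.fitness for rm in top2]


def test_separable_data_reaches_high_fitness(space):
    rng_ = np.random.default_rng(0)
    X = rng_.standard_normal((40, 4))
    y = np.arange(40) % 2
    X[y == 1] += 6.0
    data = tg.Dataset(features=X, y=y, column_names=list("abcd"))
    cfg = GAConfig(population_size=14, generations=5,
                   quotas={"selection": 1, "crossover": 4, "asexual": 2,
                           "mutation": 1, "random": 6}, seed=2)
    _, audit = run_model_selection(data, cfg, space)
    assert audit["best_fitness"] >= 0.95
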