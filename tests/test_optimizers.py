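import numpy as np
import pytest

from shiftassign.optimizers import (
    Individual,
    OptimizerConfig,
    OptimizerState,
    associate,
    crossover,
    crowding_distance,
    das_dennis_directions,
    dominates,
    ga_step,
    hill_climb,
    make_individual,
    mutate,
    niching_select,
    non_dominated_sort,
    nsga2_step,
    nsga2_survival,
    run_optimizer,
)
from shiftassign.scoring import ObjectiveVector, get_evaluator
from shiftassign.problem_model import NONE, validate_chromosome
from shiftassign.synthetic_data import SimulationConfig, make_dataset
from conftest import random_tiny_instance
from oracles import brute_crowded_truncation, brute_crowding, brute_fronts


@pytest.fixture(scope="module")
def synthetic():
    cfg = SimulationConfig(sequence_length=10, p_missing=0.2, artifact_ratio=0.5, seed=9)
    return make_dataset(cfg)


def _individual(objectives, g=0.0):
    padded = tuple(objectives) + (0.0,) * (4 - len(objectives))
    return Individual(
        chromosome=np.zeros(1, dtype=np.int64),
        objectives=ObjectiveVector(*padded),
        G=g,
    )


class TestDominance:
    def test_single_strict_improvement(self):
        assert dominates((0, 0, -3, 2), (0, 0, -2, 2))

    def test_identical_vectors_do_not_dominate(self):
        assert not dominates((1, 2, 3, 4), (1, 2, 3, 4))

    def test_incomparable_pair(self):
        assert not dominates((-1, 0, 0, 0), (0, -1, 0, 0))
        assert not dominates((0, -1, 0, 0), (-1, 0, 0, 0))


class TestNonDominatedSort:
    def test_single_individual(self):
        fronts = non_dominated_sort(np.array([[1.0, 2.0]]))
        assert [list(f) for f in fronts] == [[0]]

    def test_chain_gives_singleton_fronts(self):
        F = np.array([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]])
        fronts = non_dominated_sort(F)
        assert [list(f) for f in fronts] == [[1], [2], [0]]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_populations_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.integers(0, 5, size=(30, 4)).astype(float)
        fronts = non_dominated_sort(F)
        assert [sorted(f) for f in fronts] == brute_fronts(F.tolist())


class TestCrowdingDistance:
    def test_tiny_front_is_all_infinite(self):
        assert np.all(np.isinf(crowding_distance(np.array([[1.0, 2.0]]))))
        assert np.all(np.isinf(crowding_distance(np.array([[1.0, 2.0], [2.0, 1.0]]))))

    def test_four_collinear_points_hand_computed(self):
        F = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 3.0], [6.0, 6.0]])
        d = crowding_distance(F)
        assert d[0] == np.inf and d[3] == np.inf
        assert d[1] == pytest.approx(2 * (3 - 0) / 6)
        assert d[2] == pytest.approx(2 * (6 - 1) / 6)

    def test_duplicated_vectors_get_finite_equal_distances(self):
        F = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        d = crowding_distance(F)
        interior = sorted(d)[:3]
        assert all(np.isfinite(x) for x in interior)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(50 + seed)
        F = rng.random((12, 4))
        assert crowding_distance(F) == pytest.approx(brute_crowding(F.tolist()))


class _AlwaysSwapRng:
    def random(self, size=None):
        return np.zeros(size) if size is not None else 0.0


class TestVariationOperators:
    def test_crossover_rate_zero_copies_parents(self):
        rng = np.random.default_rng(0)
        p1 = np.array([0, 1, 2], dtype=np.int64)
        p2 = np.array([2, 1, 0], dtype=np.int64)
        c1, c2 = crossover(p1, p2, 0.0, rng)
        assert np.array_equal(c1, p1) and np.array_equal(c2, p2)

    def test_crossover_rate_one_with_always_swap_rng_is_full_exchange(self):
        p1 = np.array([0, 1, 2], dtype=np.int64)
        p2 = np.array([2, 1, 0], dtype=np.int64)
        c1, c2 = crossover(p1, p2, 1.0, _AlwaysSwapRng())
        assert np.array_equal(c1, p2) and np.array_equal(c2, p1)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("rate", [0.3, 1.0, "dynamic"])
    def test_children_always_valid(self, synthetic, seed, rate):
        inst, _ = synthetic
        rng = np.random.default_rng(seed)
        p1 = inst.random_chromosome(rng)
        p2 = inst.random_chromosome(rng)
        c1, c2 = crossover(p1, p2, rate, rng)
        assert validate_chromosome(inst, c1) == []
        assert validate_chromosome(inst, c2) == []

    def test_mutation_rate_zero_is_identity(self, synthetic):
        inst, _ = synthetic
        rng = np.random.default_rng(1)
        chrom = inst.random_chromosome(rng)
        assert np.array_equal(mutate(chrom, 0.0, rng, inst), chrom)

    @pytest.mark.parametrize("seed", range(5))
    def test_mutation_rate_one_changes_at_most_one_gene(self, synthetic, seed):
        inst, _ = synthetic
        rng = np.random.default_rng(seed)
        chrom = inst.random_chromosome(rng)
        child = mutate(chrom, 1.0, rng, inst)
        assert int((child != chrom).sum()) <= 1
        assert validate_chromosome(inst, child) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_dynamic_mutation_keeps_validity(self, synthetic, seed):
        inst, _ = synthetic
        rng = np.random.default_rng(seed)
        child = mutate(inst.random_chromosome(rng), "dynamic", rng, inst)
        assert validate_chromosome(inst, child) == []


def _make_state(instance, config, seed=0, population=None):
    evaluator = get_evaluator(instance, config.scoring)
    rng = np.random.default_rng(seed)
    if population is None:
        population = [
            make_individual(evaluator, instance.random_chromosome(rng))
            for _ in range(config.population_size)
        ]
    return OptimizerState(
        instance=instance,
        config=config,
        evaluator=evaluator,
        rng=rng,
        population=population,
    )


class TestGaStep:
    def test_elitism_never_loses_best_G(self, synthetic):
        inst, _ = synthetic
        state = _make_state(inst, OptimizerConfig(algorithm="GA", population_size=10), 3)
        best = max(ind.G for ind in state.population)
        for _ in range(20):
            ga_step(state)
            new_best = max(ind.G for ind in state.population)
            assert new_best >= best
            best = new_best

    def test_population_size_constant(self, synthetic):
        inst, _ = synthetic
        state = _make_state(inst, OptimizerConfig(algorithm="GA", population_size=10), 4)
        ga_step(state)
        assert len(state.population) == 10

    @pytest.mark.parametrize("seed", range(5))
    def test_one_gene_instance_reaches_exhaustive_optimum(self, one_gene_instance, seed):
        result = run_optimizer(
            one_gene_instance,
            OptimizerConfig(algorithm="GA", population_size=4, iterations=50, seed=seed),
        )
        # exhaustive optimum on this instance maps the peak to the means (index 1)
        assert result.reported.chromosome[0] == 1
        assert result.reported.G == pytest.approx(1.0)


class TestNsga2:
    def test_merged_population_reduced_to_n(self, synthetic):
        inst, _ = synthetic
        state = _make_state(inst, OptimizerConfig(algorithm="NSGA2", population_size=8), 5)
        nsga2_step(state)
        assert len(state.population) == 8

    def test_survival_matches_brute_force_truncation(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            F = rng.random((20, 4))
            merged = [_individual(tuple(row)) for row in F]
            survivors = nsga2_survival(merged, 10)
            chosen = [merged.index(s) for s in survivors]
            assert sorted(chosen) == sorted(brute_crowded_truncation(F.tolist(), 10))

    def test_infinite_crowding_front0_member_survives(self):
        # front 0 fits entirely: all its members survive regardless of crowding
        F = np.array([[0.0, 3.0], [1.0, 2.0], [2.0, 1.0], [3.0, 0.0], [5.0, 5.0]])
        merged = [_individual(tuple(row)) for row in F]
        survivors = nsga2_survival(merged, 4)
        assert {merged.index(s) for s in survivors} == {0, 1, 2, 3}


class TestNsga3:
    def test_das_dennis_count(self):
        dirs = das_dennis_directions(4, 6)
        assert len(dirs) == 84  # C(6+3, 3)
        assert np.allclose(dirs.sum(axis=1), 1.0)

    def test_member_on_reference_ray_has_zero_distance(self):
        dirs = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        member = np.array([[0.3, 0.3]])
        pi, d = associate(member, dirs)
        assert pi[0] == 2
        assert d[0] == pytest.approx(0.0, abs=1e-6)

    def test_niche_counts_conserved(self):
        rng = np.random.default_rng(0)
        dirs = das_dennis_directions(4, 4)
        members = rng.random((25, 4))
        pi, d = associate(members, dirs)
        counts = np.bincount(pi, minlength=len(dirs))
        assert counts.sum() == 25

    def test_niching_hand_trace(self):
        # 8 last-front members, 3 slots, 4 reference directions, no count ties
        pi = np.array([1, 1, 0, 2, 3, 3, 3, 3])
        d = np.array([0.1, 0.05, 0.2, 0.3, 0.25, 0.4, 0.1, 0.2])
        niche_counts = np.array([4, 0, 3, 5], dtype=np.int64)
        rng = np.random.default_rng(0)
        chosen = niching_select(list(range(8)), 3, pi, d, niche_counts, rng)
        # dir 1 empty -> closest member (1), then member 0; dir 2 next -> member 3
        assert chosen == [1, 0, 3]
        assert niche_counts.tolist() == [4, 2, 4, 5]

    def test_step_keeps_population_size_and_validity(self, synthetic):
        inst, _ = synthetic
        from shiftassign.optimizers import nsga3_step

        state = _make_state(inst, OptimizerConfig(algorithm="NSGA3", population_size=8), 6)
        for _ in range(3):
            nsga3_step(state)
            assert len(state.population) == 8
            for ind in state.population:
                assert validate_chromosome(inst, ind.chromosome) == []


class TestHillClimb:
    def test_locally_optimal_chromosome_unchanged(self, one_gene_instance):
        best = np.array([1], dtype=np.int64)
        assert np.array_equal(hill_climb(one_gene_instance, best), best)

    def test_misassigned_gene_corrected_to_exhaustive_optimum(self, one_gene_instance):
        assert hill_climb(one_gene_instance, np.array([0], dtype=np.int64))[0] == 1
        assert hill_climb(one_gene_instance, np.array([NONE], dtype=np.int64))[0] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_G_never_decreases(self, synthetic, seed):
        inst, _ = synthetic
        evaluator = get_evaluator(inst)
        rng = np.random.default_rng(seed)
        chrom = inst.random_chromosome(rng)
        improved = hill_climb(inst, chrom)
        assert evaluator.evaluate(improved)[1] >= evaluator.evaluate(chrom)[1]
        assert validate_chromosome(inst, improved) == []


class TestRunOptimizer:
    def test_zero_iterations_reports_best_initial(self, synthetic):
        inst, _ = synthetic
        result = run_optimizer(
            inst, OptimizerConfig(algorithm="GA", population_size=6, iterations=0, seed=2)
        )
        assert result.reported.G == max(ind.G for ind in result.population)
        assert result.traces["best_G"].shape == (1,)

    @pytest.mark.parametrize("algorithm", ["GA", "NSGA2", "NSGA3"])
    def test_fixed_seed_reproducible(self, synthetic, algorithm):
        inst, _ = synthetic
        cfg = OptimizerConfig(
            algorithm=algorithm, population_size=6, iterations=5, seed=11
        )
        a = run_optimizer(inst, cfg)
        b = run_optimizer(inst, cfg)
        assert np.array_equal(a.reported.chromosome, b.reported.chromosome)
        assert np.array_equal(a.traces["best_G"], b.traces["best_G"])

    def test_ga_improves_over_mean_initial_score(self, synthetic):
        inst, _ = synthetic
        for seed in range(5):
            cfg = OptimizerConfig(
                algorithm="GA", population_size=10, iterations=60, seed=seed
            )
            result = run_optimizer(inst, cfg)
            assert result.reported.G > result.traces["best_G"][0] - 1e-12
            mean_initial = np.mean(
                [ind.G for ind in run_optimizer(
                    inst, OptimizerConfig(algorithm="GA", population_size=10,
                                          iterations=0, seed=seed)
                ).population]
            )
            assert result.reported.G > mean_initial

    def test_hyper_heuristic_best_G_trace_monotone(self, synthetic):
        inst, _ = synthetic
        cfg = OptimizerConfig(
            algorithm="GA", population_size=6, iterations=8,
            hill_climb_each_iteration=True, seed=0,
        )
        trace = run_optimizer(inst, cfg).traces["best_G"]
        assert np.all(np.diff(trace) >= -1e-12)
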