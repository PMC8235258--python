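"""Evolutionary search over assignment chromosomes.

Three algorithms share the variation operators:

* ``GA``     — single-objective: the four objectives are min–max normalized
  within the current population and averaged with equal weights into one
  scalar fitness (ties broken by the global score G); binary-tournament
  selection with elitism on G.
* ``NSGA2``  — non-dominated sorting, crowding distance, crowded-comparison
  binary tournaments, elitist (μ+λ) survival.
* ``NSGA3``  — non-dominated sorting plus reference-direction niching on a
  Das–Dennis lattice with ideal-point/intercept normalization.

Crossover is a uniform per-gene exchange applied with probability
``crossover_rate``; mutation resets one uniformly chosen gene to a uniform
draw from {unassigned} ∪ same-spectrum measured indices (the dynamic rate
``1/L`` instead resets every gene independently with probability 1/L).  Both
operators preserve chromosome validity by construction.  A hill-climbing pass
greedily improves single genes under G and can optionally follow every
evolutionary iteration (the hyper-heuristic combination).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .constructive_init import InitConfig, build_population
from .peak_io import ValidationError
from .problem_model import NONE, Chromosome, ProblemInstance
from .scoring import Evaluator, ObjectiveVector, ScoringConfig, get_evaluator

logger = logging.getLogger(__name__)

Rate = Union[float, str]  #: a probability in [0, 1] or the marker "dynamic" (= 1/L)


@dataclass(frozen=True)
class OptimizerConfig:
    algorithm: str = "GA"
    population_size: int = 50
    iterations: int = 10_000
    crossover_rate: Rate = 1.0
    mutation_rate: Rate = 1.0
    hill_climb_each_iteration: bool = False
    nsga3_divisions: int = 6
    seed: Optional[int] = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if self.algorithm.upper() not in ("GA", "NSGA2", "NSGA3"):
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.population_size < 2 or self.population_size % 2:
            raise ValidationError("population_size must be even and >= 2")
        for name, rate in (("crossover_rate", self.crossover_rate),
                           ("mutation_rate", self.mutation_rate)):
            if isinstance(rate, str):
                if rate != "dynamic":
                    raise ValidationError(f"{name}: {rate!r} is not 'dynamic'")
            elif not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass(eq=False)
class Individual:
    """A chromosome together with its cached objective values."""

    chromosome: Chromosome
    objectives: ObjectiveVector
    G: float
    rank: Optional[int] = None
    crowding: Optional[float] = None

    @property
    def F(self) -> np.ndarray:
        return np.asarray(self.objectives, dtype=float)


@dataclass
class RunResult:
    """Outcome of one optimizer run."""

    population: list[Individual]
    reported: Individual
    traces: dict[str, np.ndarray]


def make_individual(evaluator: Evaluator, chromosome: Chromosome) -> Individual:
    objectives, g = evaluator.evaluate(chromosome)
    return Individual(chromosome=chromosome, objectives=objectives, G=g)


# ---------------------------------------------------------------------------
# Pareto machinery
# ---------------------------------------------------------------------------


def dominates(u: Sequence[float], v: Sequence[float]) -> bool:
    """Pareto dominance for minimization: u ≤ v everywhere, < somewhere."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("objective vectors differ in length")
    return bool(np.all(u <= v) and np.any(u < v))


def non_dominated_sort(objectives: np.ndarray) -> list[np.ndarray]:
    """Partition row indices of an (N, M) objective matrix into Pareto fronts."""
    F = np.asarray(objectives, dtype=float)
    n = F.shape[0]
    # pairwise dominance: dom[i, j] = i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    dominated_by = [np.flatnonzero(dom[i]) for i in range(n)]
    fronts: list[np.ndarray] = []
    current = np.flatnonzero(n_dominators == 0)
    remaining = n_dominators.copy()
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                remaining[j] -= 1
                if remaining[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(nxt), dtype=np.int64)
    return fronts


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance of one front's (n, M) objective matrix.

    Boundary members per objective get +inf; interior members accumulate the
    normalized gap between their neighbours; objectives with zero range
    contribute nothing.
    """
    F = np.asarray(objectives, dtype=float)
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        col = F[order, j]
        span = col[-1] - col[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (col[2:] - col[:-2]) / span
    return dist


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------


def crossover(
    parent1: Chromosome,
    parent2: Chromosome,
    rate: Rate,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome]:
    """Uniform per-gene exchange with application probability ``rate``."""
    length = len(parent1)
    p = 1.0 / length if rate == "dynamic" else float(rate)
    child1 = parent1.copy()
    child2 = parent2.copy()
    if p > 0 and rng.random() < p:
        swap = rng.random(length) < 0.5
        child1[swap] = parent2[swap]
        child2[swap] = parent1[swap]
    return child1, child2


def mutate(
    chromosome: Chromosome,
    rate: Rate,
    rng: np.random.Generator,
    instance: ProblemInstance,
) -> Chromosome:
    """Gene reset mutation.

    Static rate: with probability ``rate``, one uniformly chosen gene is
    redrawn uniformly from {NONE} ∪ same-spectrum measured indices.  Dynamic
    rate: every gene is independently redrawn with probability 1/L.
    """
    child = chromosome.copy()
    counts = instance.gene_measured_count
    if rate == "dynamic":
        hits = np.flatnonzero(rng.random(instance.L) < 1.0 / instance.L)
        for g in hits:
            child[g] = rng.integers(-1, counts[g])
    elif rng.random() < float(rate):
        g = int(rng.integers(instance.L))
        child[g] = rng.integers(-1, counts[g])
    return child


# ---------------------------------------------------------------------------
# Optimizer state and per-iteration steps
# ---------------------------------------------------------------------------


@dataclass
class OptimizerState:
    instance: ProblemInstance
    config: OptimizerConfig
    evaluator: Evaluator
    rng: np.random.Generator
    population: list[Individual]
    reference_directions: Optional[np.ndarray] = None
    iteration: int = 0


def scalar_fitness(population: Sequence[Individual]) -> np.ndarray:
    """GA scalarization: equal-weight mean of min–max-normalized objectives."""
    F = np.array([ind.F for ind in population])
    lo = F.min(axis=0)
    span = F.max(axis=0) - lo
    span[span == 0] = 1.0
    return ((F - lo) / span).mean(axis=1)


def _pair_children(
    state: OptimizerState, parent_pairs: list[tuple[Individual, Individual]]
) -> list[Individual]:
    cfg = state.config
    children: list[Individual] = []
    for p1, p2 in parent_pairs:
        c1, c2 = crossover(p1.chromosome, p2.chromosome, cfg.crossover_rate, state.rng)
        c1 = mutate(c1, cfg.mutation_rate, state.rng, state.instance)
        c2 = mutate(c2, cfg.mutation_rate, state.rng, state.instance)
        children.append(make_individual(state.evaluator, c1))
        children.append(make_individual(state.evaluator, c2))
    return children


def ga_step(state: OptimizerState) -> OptimizerState:
    """One GA generation: tournaments on scalar fitness, variation, elitism."""
    pop = state.population
    n = len(pop)
    fitness = scalar_fitness(pop)

    def tournament() -> Individual:
        i, j = state.rng.integers(n, size=2)
        key_i = (fitness[i], -pop[i].G)
        key_j = (fitness[j], -pop[j].G)
        return pop[i] if key_i <= key_j else pop[j]

    pairs = [(tournament(), tournament()) for _ in range(n // 2)]
    children = _pair_children(state, pairs)
    elite = max(pop, key=lambda ind: ind.G)
    best_child = max(children, key=lambda ind: ind.G)
    if best_child.G < elite.G:
        worst = min(range(n), key=lambda k: children[k].G)
        children[worst] = elite
    state.population = children
    state.iteration += 1
    return state


def _assign_ranks_and_crowding(population: list[Individual]) -> list[np.ndarray]:
    F = np.array([ind.F for ind in population])
    fronts = non_dominated_sort(F)
    for rank, front in enumerate(fronts):
        dist = crowding_distance(F[front])
        for k, idx in enumerate(front):
            population[idx].rank = rank
            population[idx].crowding = float(dist[k])
    return fronts


def nsga2_survival(merged: list[Individual], n_keep: int) -> list[Individual]:
    """Fill whole fronts in rank order; truncate the last by crowding distance."""
    F = np.array([ind.F for ind in merged])
    fronts = non_dominated_sort(F)
    survivors: list[Individual] = []
    for rank, front in enumerate(fronts):
        dist = crowding_distance(F[front])
        for k, idx in enumerate(front):
            merged[idx].rank = rank
            merged[idx].crowding = float(dist[k])
        if len(survivors) + len(front) <= n_keep:
            survivors.extend(merged[idx] for idx in front)
        else:
            order = np.argsort(-dist, kind="stable")
            need = n_keep - len(survivors)
            survivors.extend(merged[front[i]] for i in order[:need])
        if len(survivors) == n_keep:
            break
    return survivors


def nsga2_step(state: OptimizerState) -> OptimizerState:
    """One NSGA-II generation with crowded-comparison tournaments."""
    pop = state.population
    n = len(pop)
    if any(ind.rank is None for ind in pop):
        _assign_ranks_and_crowding(pop)

    def tournament() -> Individual:
        i, j = state.rng.integers(n, size=2)
        a, b = pop[i], pop[j]
        if a.rank != b.rank:
            return a if a.rank < b.rank else b
        return a if a.crowding >= b.crowding else b

    pairs = [(tournament(), tournament()) for _ in range(n // 2)]
    children = _pair_children(state, pairs)
    state.population = nsga2_survival(pop + children, n)
    state.iteration += 1
    return state


# -- NSGA-III -----------------------------------------------------------------


def das_dennis_directions(n_objectives: int, divisions: int) -> np.ndarray:
    """Das–Dennis simplex lattice: all compositions of ``divisions`` parts."""
    points = []
    for comp in itertools.combinations_with_replacement(range(n_objectives), divisions):
        counts = np.bincount(np.array(comp, dtype=np.int64), minlength=n_objectives)
        points.append(counts / divisions)
    return np.unique(np.array(points), axis=0)


def _normalize_objectives(F: np.ndarray) -> np.ndarray:
    """Translate by the ideal point and scale by extreme-point intercepts.

    Falls back to per-objective range normalization when the extreme-point
    hyperplane is degenerate.
    """
    ideal = F.min(axis=0)
    T = F - ideal
    m = F.shape[1]
    extremes = np.empty(m, dtype=np.int64)
    for j in range(m):
        weights = np.full(m, 1e-6)
        weights[j] = 1.0
        asf = (T / weights).max(axis=1)
        extremes[j] = int(np.argmin(asf))
    intercepts = None
    E = T[extremes]
    try:
        coeffs = np.linalg.solve(E, np.ones(m))
        candidate = 1.0 / coeffs
        if np.all(np.isfinite(candidate)) and np.all(candidate > 1e-12):
            intercepts = candidate
    except np.linalg.LinAlgError:
        pass
    if intercepts is None:
        logger.debug("degenerate extreme-point hyperplane; range normalization")
        intercepts = T.max(axis=0)
        intercepts[intercepts <= 1e-12] = 1.0
    return T / intercepts


def associate(normalized: np.ndarray, directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference direction by perpendicular distance: (π, d) per member."""
    unit = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    proj = normalized @ unit.T  # (N, R) scalar projections
    # squared perpendicular distance ||f||² − proj²
    sq = (normalized**2).sum(axis=1, keepdims=True) - proj**2
    sq = np.maximum(sq, 0.0)
    pi = np.argmin(sq, axis=1)
    d = np.sqrt(sq[np.arange(len(normalized)), pi])
    return pi, d


def niching_select(
    last_front: list[int],
    n_slots: int,
    pi: np.ndarray,
    d: np.ndarray,
    niche_counts: np.ndarray,
    rng: np.random.Generator,
) -> list[int]:
    """Pick ``n_slots`` members of the last front by ascending niche count.

    ``pi``/``d`` index all merged members; ``niche_counts`` counts the already
    accepted members per reference direction and is updated in place.  For an
    empty niche the closest member is taken, otherwise a random one; exhausted
    directions are excluded.  Ties between directions break uniformly at
    random.
    """
    chosen: list[int] = []
    available = set(last_front)
    active = {int(j) for j in range(len(niche_counts))}
    by_dir: dict[int, list[int]] = {}
    for idx in last_front:
        by_dir.setdefault(int(pi[idx]), []).append(idx)
    while len(chosen) < n_slots:
        counts = [(niche_counts[j], j) for j in sorted(active)]
        min_count = min(c for c, _ in counts)
        candidates = [j for c, j in counts if c == min_count]
        j = int(candidates[rng.integers(len(candidates))])
        cluster = [idx for idx in by_dir.get(j, ()) if idx in available]
        if not cluster:
            active.discard(j)
            continue
        if niche_counts[j] == 0:
            pick = min(cluster, key=lambda idx: (d[idx], idx))
        else:
            pick = cluster[int(rng.integers(len(cluster)))]
        chosen.append(pick)
        available.discard(pick)
        niche_counts[j] += 1
    return chosen


def nsga3_survival(
    merged: list[Individual],
    n_keep: int,
    directions: np.ndarray,
    rng: np.random.Generator,
) -> list[Individual]:
    F = np.array([ind.F for ind in merged])
    fronts = non_dominated_sort(F)
    for rank, front in enumerate(fronts):
        for idx in front:
            merged[idx].rank = rank
    accepted: list[int] = []
    last: np.ndarray = fronts[0]
    for front in fronts:
        if len(accepted) + len(front) <= n_keep:
            accepted.extend(int(i) for i in front)
            last = front
            if len(accepted) == n_keep:
                return [merged[i] for i in accepted]
        else:
            last = front
            break
    considered = accepted + [int(i) for i in last]
    normalized = _normalize_objectives(F[considered])
    pi_all, d_all = associate(normalized, directions)
    pi = np.empty(len(merged), dtype=np.int64)
    d = np.empty(len(merged))
    for local, idx in enumerate(considered):
        pi[idx] = pi_all[local]
        d[idx] = d_all[local]
    niche_counts = np.zeros(len(directions), dtype=np.int64)
    for idx in accepted:
        niche_counts[pi[idx]] += 1
    chosen = niching_select(
        [int(i) for i in last], n_keep - len(accepted), pi, d, niche_counts, rng
    )
    return [merged[i] for i in accepted + chosen]


def nsga3_step(state: OptimizerState) -> OptimizerState:
    """One NSGA-III generation: unselective variation, then niching survival."""
    pop = state.population
    n = len(pop)
    if state.reference_directions is None:
        state.reference_directions = das_dennis_directions(4, state.config.nsga3_divisions)
    order = state.rng.permutation(n)
    pairs = [(pop[order[k]], pop[order[k + 1]]) for k in range(0, n, 2)]
    children = _pair_children(state, pairs)
    state.population = nsga3_survival(
        pop + children, n, state.reference_directions, state.rng
    )
    state.iteration += 1
    return state


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------


def hill_climb(
    instance: ProblemInstance,
    chromosome: Chromosome,
    config: Optional[ScoringConfig] = None,
) -> Chromosome:
    """One best-improvement pass over all genes under the global score G.

    Every gene in index order is tentatively reassigned to each value in
    {NONE} ∪ same-spectrum measured indices and the strictly best improvement
    is kept; G never decreases.
    """
    evaluator = get_evaluator(instance, config)
    current = chromosome.copy()
    _, best_g = evaluator.evaluate(current)
    for g in range(instance.L):
        original = current[g]
        best_value = original
        for value in range(-1, int(instance.gene_measured_count[g])):
            if value == original:
                continue
            current[g] = value
            _, score = evaluator.evaluate(current)
            if score > best_g:
                best_g = score
                best_value = value
        current[g] = best_value
    return current


# ---------------------------------------------------------------------------
# Run loop
# ---------------------------------------------------------------------------

_STEPS = {"GA": ga_step, "NSGA2": nsga2_step, "NSGA3": nsga3_step}


def run_optimizer(
    instance: ProblemInstance,
    config: OptimizerConfig = OptimizerConfig(),
    init_config: Optional[InitConfig] = None,
) -> RunResult:
    """Initialize constructively and evolve for ``config.iterations`` steps.

    Records the per-iteration population minimum of each objective and the
    maximum G.  The reported individual is the maximal-G member of the final
    population (restricted to the first non-dominated front for NSGA2/NSGA3).
    """
    rng = np.random.default_rng(config.seed)
    if init_config is None:
        init_config = InitConfig(population_size=config.population_size)
    elif init_config.population_size != config.population_size:
        init_config = InitConfig(
            population_size=config.population_size,
            random_fraction=init_config.random_fraction,
            k_sigma=init_config.k_sigma,
        )
    evaluator = get_evaluator(instance, config.scoring)
    chromosomes = build_population(instance, init_config, rng=rng)
    population = [make_individual(evaluator, c) for c in chromosomes]
    state = OptimizerState(
        instance=instance,
        config=config,
        evaluator=evaluator,
        rng=rng,
        population=population,
    )
    step = _STEPS[config.algorithm.upper()]

    n_iter = config.iterations
    trace_F = np.empty((n_iter + 1, 4))
    trace_G = np.empty(n_iter + 1)

    def record(k: int) -> None:
        F = np.array([ind.F for ind in state.population])
        trace_F[k] = F.min(axis=0)
        trace_G[k] = max(ind.G for ind in state.population)

    record(0)
    for k in range(1, n_iter + 1):
        step(state)
        if config.hill_climb_each_iteration:
            best = max(range(len(state.population)), key=lambda i: state.population[i].G)
            improved = hill_climb(
                instance, state.population[best].chromosome, config.scoring
            )
            state.population[best] = make_individual(evaluator, improved)
        record(k)

    final = state.population
    if config.algorithm.upper() in ("NSGA2", "NSGA3"):
        F = np.array([ind.F for ind in final])
        front0 = non_dominated_sort(F)[0]
        reported = max((final[int(i)] for i in front0), key=lambda ind: ind.G)
    else:
        reported = max(final, key=lambda ind: ind.G)
    return RunResult(
        population=final,
        reported=reported,
        traces={"min_objectives": trace_F, "best_G": trace_G},
    )
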