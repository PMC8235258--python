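"""Multi-run consolidation and evaluation against a reference shift list.

An algorithm is run R times with different random seeds; each run's reported
chromosome is projected to a per-atom shift list (value = δ̄(a)).  The R
values of each atom are merged by single-linkage clustering at the atom's
nucleus tolerance; the consensus shift is the mean of the largest cluster
(ties: smaller spread, then lower mean).

Against a reference list, an atom is *correct* when its consensus deviates
from the reference by strictly less than the tolerance, *wrong* when assigned
but off by at least the tolerance, and *unassigned* otherwise.  Atoms missing
from the reference are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .optimizers import OptimizerConfig, RunResult, run_optimizer
from .peak_io import AtomId, ShiftList, ValidationError
from .problem_model import ProblemInstance, ToleranceConfig
from .scoring import chromosome_shift_list
from .constructive_init import InitConfig

CORRECT = "correct"
WRONG = "wrong"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RepetitionConfig:
    """How many independent optimizer executions feed the consolidation."""

    repetitions: int = 10
    seeds: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if self.seeds is not None and len(self.seeds) != self.repetitions:
            raise ValidationError("seeds must match the repetition count")


@dataclass
class EvaluationReport:
    """Correct / wrong / unassigned accounting against a reference list."""

    verdicts: dict[AtomId, str]
    deviations: dict[AtomId, float] = field(default_factory=dict)

    @property
    def n_reference(self) -> int:
        return len(self.verdicts)

    def count(self, verdict: str) -> int:
        return sum(1 for v in self.verdicts.values() if v == verdict)

    def percentage(self, verdict: str) -> float:
        if not self.verdicts:
            return 0.0
        return 100.0 * self.count(verdict) / len(self.verdicts)

    @property
    def correct_atoms(self) -> set[AtomId]:
        return {a for a, v in self.verdicts.items() if v == CORRECT}

    def summary(self) -> str:
        total = self.n_reference
        parts = [
            f"{label}: {self.count(label)}/{total} ({self.percentage(label):.1f}%)"
            for label in (CORRECT, WRONG, UNASSIGNED)
        ]
        return "; ".join(parts)


def _single_linkage_clusters(values: np.ndarray, threshold: float) -> list[np.ndarray]:
    """1-D single-linkage clusters: split sorted values at gaps > threshold."""
    order = np.argsort(values, kind="stable")
    ordered = values[order]
    breaks = np.flatnonzero(np.diff(ordered) > threshold) + 1
    return [order[chunk] for chunk in np.split(np.arange(len(values)), breaks)]


def consolidate(
    shift_lists: Sequence[ShiftList], tolerances: ToleranceConfig = ToleranceConfig()
) -> ShiftList:
    """Merge per-run shift lists into a consensus list.

    Per atom, runs in which the atom is absent are skipped; the remaining
    values are single-linkage clustered at the atom's tolerance and the
    consensus is the mean of the largest cluster (ties broken by smaller
    spread, then lower mean).  Atoms absent from every run stay absent.
    """
    if not shift_lists:
        raise ValidationError("need at least one shift list")
    atoms = sorted({a for sl in shift_lists for a in sl.entries})
    entries: dict[AtomId, tuple[float, Optional[float]]] = {}
    for atom in atoms:
        values = np.array(
            [sl.entries[atom][0] for sl in shift_lists if atom in sl.entries]
        )
        tol = tolerances.for_atom(atom)
        clusters = _single_linkage_clusters(values, tol)
        best = min(
            clusters,
            key=lambda idx: (
                -len(idx),
                float(np.ptp(values[idx])),
                float(np.mean(values[idx])),
            ),
        )
        member_values = values[best]
        entries[atom] = (float(np.mean(member_values)), float(np.std(member_values)))
    return ShiftList(entries=entries)


def evaluate(
    consensus: ShiftList,
    reference: ShiftList,
    tolerances: ToleranceConfig = ToleranceConfig(),
) -> EvaluationReport:
    """Classify every reference atom as correct, wrong or unassigned.

    The boundary is strict: a deviation exactly equal to the tolerance counts
    as wrong.
    """
    verdicts: dict[AtomId, str] = {}
    deviations: dict[AtomId, float] = {}
    for atom, (ref_shift, _) in reference.entries.items():
        if atom not in consensus:
            verdicts[atom] = UNASSIGNED
            continue
        delta = abs(consensus.shift(atom) - ref_shift)
        deviations[atom] = delta
        verdicts[atom] = CORRECT if delta < tolerances.for_atom(atom) else WRONG
    return EvaluationReport(verdicts=verdicts, deviations=deviations)


def mutual_agreement(
    reports: dict[str, EvaluationReport],
) -> dict[frozenset[str], tuple[int, float]]:
    """Venn partition of correctly assigned atoms across algorithms.

    For every non-empty subset of algorithm names, counts the atoms correct
    in exactly that subset; percentages are relative to the union of all
    correctly assigned atoms.
    """
    if len(reports) < 2:
        raise ValidationError("need at least two reports")
    registries = {frozenset(r.verdicts) for r in reports.values()}
    if len(registries) != 1:
        raise ValidationError("reports cover different atom registries")
    correct_sets = {name: r.correct_atoms for name, r in reports.items()}
    union = set().union(*correct_sets.values())
    table: dict[frozenset[str], tuple[int, float]] = {}
    names = sorted(reports)
    from itertools import combinations

    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            inside = set(union)
            for name in subset:
                inside &= correct_sets[name]
            for name in names:
                if name not in subset:
                    inside -= correct_sets[name]
            pct = 100.0 * len(inside) / len(union) if union else 0.0
            table[frozenset(subset)] = (len(inside), pct)
    return table


def run_pipeline(
    instance: ProblemInstance,
    optimizer_config: OptimizerConfig = OptimizerConfig(),
    repetition_config: RepetitionConfig = RepetitionConfig(),
    init_config: Optional[InitConfig] = None,
    reference: Optional[ShiftList] = None,
) -> tuple[ShiftList, Optional[EvaluationReport], list[RunResult]]:
    """R independent optimizer runs → per-run shift lists → consensus.

    Per-repetition seeds come from ``repetition_config.seeds`` or are spawned
    deterministically from ``optimizer_config.seed``.
    """
    R = repetition_config.repetitions
    if repetition_config.seeds is not None:
        seeds = list(repetition_config.seeds)
    else:
        ss = np.random.SeedSequence(optimizer_config.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(R)]
    results: list[RunResult] = []
    per_run: list[ShiftList] = []
    for seed in seeds:
        cfg = OptimizerConfig(
            algorithm=optimizer_config.algorithm,
            population_size=optimizer_config.population_size,
            iterations=optimizer_config.iterations,
            crossover_rate=optimizer_config.crossover_rate,
            mutation_rate=optimizer_config.mutation_rate,
            hill_climb_each_iteration=optimizer_config.hill_climb_each_iteration,
            nsga3_divisions=optimizer_config.nsga3_divisions,
            seed=seed,
            scoring=optimizer_config.scoring,
        )
        result = run_optimizer(instance, cfg, init_config)
        results.append(result)
        per_run.append(chromosome_shift_list(instance, result.reported.chromosome))
    consensus = consolidate(per_run, instance.tolerances)
    report = (
        evaluate(consensus, reference, instance.tolerances)
        if reference is not None
        else None
    )
    return consensus, report, results
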