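"""Assignment scoring: the four objectives and the aggregated global score.

A candidate assignment induces, for every atom *a* touched by a mapped
expected peak, a list of ppm contributions p(a, n) — one per (peak, dimension)
slot — with arithmetic mean δ̄(a).  Two Gaussian quality kernels grade each
atom and each contribution:

* shift normality  Q1(a)   = exp(−(δ̄(a) − μ_a)² / (2 σ_a²)), from the
  per-(residue type, atom name) statistics table;
* alignment        Q2(a,n) = exp(−(p(a,n) − δ̄(a))² / (2 t_a²)), with t_a the
  experimental tolerance of the atom's nucleus.

Both kernels lie in (0, 1] and peak at perfect agreement.  The degeneracy
b(n) of a mapped expected peak n counts the expected peaks of the same
spectrum mapped to the same measured peak (itself included).

The four minimization objectives are::

    F1 = −Σ_{a∈A} Q1(a)
    F2 = −Σ_{a∈A} Σ_{n∈N'_a} Q2(a,n)
    F3 = −|A|
    F4 =  Σ_{a∈A} Σ_{n∈N'_a} b(n)

(A = assigned atoms, N'_a = mapped expected peaks touching a; no weights).
The single-objective global score aggregates them as::

    G = [Σ_{a∈A} w1·Q1(a) + Σ_{a∈A} Σ_{n∈N'_a} w2·Q2(a,n)/b(n)] / D
    D = Σ_{a∈A0} w1 + Σ_{a∈A0} Σ_{n∈N_a} w2

with defaults w1 = 4 and w2 = 1; the denominator runs over all atoms A0 and
all expected peaks, so G ∈ [0, 1] and G = 1 only for a complete,
non-degenerate, perfectly normal and aligned assignment.  Atoms without a
statistics entry contribute Q1 = 0 but still count in |A| and in D.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .peak_io import AtomId, ValidationError
from .problem_model import NONE, Chromosome, ProblemInstance, project_atom_shifts

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    """Weights of the aggregated global score."""

    w1: float = 4.0
    w2: float = 1.0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValidationError("weights must be non-negative")


class ObjectiveVector(NamedTuple):
    """The four minimization objectives of an assignment."""

    F1: float
    F2: float
    F3: float
    F4: float


def gaussian_kernel(x: float, center: float, width: float) -> float:
    """exp(−(x−center)²/(2·width²)), the quality kernel behind Q1 and Q2."""
    z = (x - center) / width
    return math.exp(-0.5 * z * z)


class Evaluator:
    """Vectorized objective/score evaluation for one problem instance.

    The evaluator flattens every (gene, dimension) pair into a *slot* and
    precomputes, per slot, the column of measured ppm values it can take, so
    that a chromosome is scored with a handful of numpy gathers and bincounts.
    """

    def __init__(self, instance: ProblemInstance, config: Optional[ScoringConfig] = None):
        self.instance = instance
        self.config = config or ScoringConfig()
        slot_gene: list[int] = []
        slot_atom: list[int] = []
        slot_offset: list[int] = []
        columns: list[np.ndarray] = []
        column_start: dict[tuple[int, int], int] = {}
        size = 0
        for g, (si, _) in enumerate(instance.genes):
            atoms = instance.gene_atoms[g]
            for d in range(len(atoms)):
                key = (si, d)
                if key not in column_start:
                    column_start[key] = size
                    col = instance.measured_positions[si][:, d]
                    columns.append(col)
                    size += len(col)
                slot_gene.append(g)
                slot_atom.append(int(atoms[d]))
                slot_offset.append(column_start[key])
        self.slot_gene = np.array(slot_gene, dtype=np.int64)
        self.slot_atom = np.array(slot_atom, dtype=np.int64)
        self.slot_offset = np.array(slot_offset, dtype=np.int64)
        self.values = np.concatenate(columns) if columns else np.zeros(0)
        self.n_slots = len(self.slot_gene)

        # spectrum-global measured-peak keys for degeneracy counting
        counts = instance.measured_counts
        self.spec_start = np.concatenate(([0], np.cumsum(counts)))[:-1]
        self.total_measured = int(counts.sum())
        self.gene_spec_start = self.spec_start[instance.gene_spectrum] if instance.L else np.zeros(0, dtype=np.int64)

        self.n_atoms = instance.n_atoms
        self.atom_tol = instance.atom_tol
        self.atom_mu = instance.atom_mu
        self.atom_sigma = instance.atom_sigma
        self.has_stats = ~np.isnan(self.atom_mu)
        missing = [a for a, ok in zip(instance.atoms, self.has_stats) if not ok]
        if missing:
            logger.info(
                "%d atoms lack shift statistics and contribute Q1 = 0: %s",
                len(missing), ", ".join(str(a) for a in missing[:10]),
            )
        # denominator of G: every atom once, every (atom, peak) slot once
        self.denominator = self.config.w1 * self.n_atoms + self.config.w2 * self.n_slots

    def evaluate(self, chromosome: Chromosome) -> tuple[ObjectiveVector, float]:
        """Return (F1..F4, G) for one chromosome."""
        if self.n_atoms == 0:
            raise ValidationError("empty instance: no atoms in any expected peak")
        chrom = np.asarray(chromosome, dtype=np.int64)
        gene_mapped = chrom != NONE
        slot_mapped = gene_mapped[self.slot_gene]
        if not slot_mapped.any():
            return ObjectiveVector(0.0, 0.0, 0.0, 0.0), 0.0

        sg = self.slot_gene[slot_mapped]
        sa = self.slot_atom[slot_mapped]
        vals = self.values[self.slot_offset[slot_mapped] + chrom[sg]]

        cnt = np.bincount(sa, minlength=self.n_atoms)
        ssum = np.bincount(sa, weights=vals, minlength=self.n_atoms)
        assigned = cnt > 0
        mean = np.zeros(self.n_atoms)
        mean[assigned] = ssum[assigned] / cnt[assigned]

        scored = assigned & self.has_stats
        z1 = (mean[scored] - self.atom_mu[scored]) / self.atom_sigma[scored]
        q1 = np.exp(-0.5 * z1 * z1)
        sum_q1 = float(q1.sum())

        z2 = (vals - mean[sa]) / self.atom_tol[sa]
        q2 = np.exp(-0.5 * z2 * z2)
        sum_q2 = float(q2.sum())

        # degeneracy: same-spectrum genes sharing a measured peak
        keys = self.gene_spec_start[gene_mapped] + chrom[gene_mapped]
        key_counts = np.bincount(keys, minlength=self.total_measured)
        b_gene = np.zeros(self.instance.L, dtype=np.int64)
        b_gene[gene_mapped] = key_counts[keys]
        b_slot = b_gene[sg]

        F1 = -sum_q1
        F2 = -sum_q2
        F3 = -float(assigned.sum())
        F4 = float(b_slot.sum())
        numerator = self.config.w1 * sum_q1 + self.config.w2 * float((q2 / b_slot).sum())
        return ObjectiveVector(F1, F2, F3, F4), numerator / self.denominator

    def degeneracy(self, chromosome: Chromosome) -> np.ndarray:
        """b(n) per gene (0 for unmapped genes)."""
        chrom = np.asarray(chromosome, dtype=np.int64)
        gene_mapped = chrom != NONE
        b_gene = np.zeros(self.instance.L, dtype=np.int64)
        if gene_mapped.any():
            keys = self.gene_spec_start[gene_mapped] + chrom[gene_mapped]
            key_counts = np.bincount(keys, minlength=self.total_measured)
            b_gene[gene_mapped] = key_counts[keys]
        return b_gene


def get_evaluator(instance: ProblemInstance, config: Optional[ScoringConfig] = None) -> Evaluator:
    """Cached evaluator for an instance (keyed by the scoring weights)."""
    cfg = config or ScoringConfig()
    key = (cfg.w1, cfg.w2)
    if key not in instance._evaluators:
        instance._evaluators[key] = Evaluator(instance, cfg)
    return instance._evaluators[key]


# ---------------------------------------------------------------------------
# Spec-level operations (scalar, readable; the Evaluator is the fast path)
# ---------------------------------------------------------------------------


def shift_normality_Q1(instance: ProblemInstance, atom: AtomId, mean_shift: float) -> float:
    """Shift normality of one assigned atom against its statistics entry.

    Atoms lacking a statistics entry score 0 (they still count as assigned).
    """
    rtype = instance.residue_type_of(atom)
    if (rtype, atom.name) not in instance.statistics:
        return 0.0
    mu, sigma = instance.statistics.get(rtype, atom.name)
    return gaussian_kernel(mean_shift, mu, sigma)


def alignment_Q2(
    instance: ProblemInstance, atom: AtomId, contribution_ppm: float, mean_shift: float
) -> float:
    """Alignment of one ppm contribution with the atom's mean shift."""
    tol = instance.tolerances.for_atom(atom)
    return gaussian_kernel(contribution_ppm, mean_shift, tol)


def degeneracy_b(instance: ProblemInstance, chromosome: Chromosome, gene: int) -> int:
    """Number of same-spectrum genes mapped to the same measured peak as ``gene``."""
    if int(chromosome[gene]) == NONE:
        raise ValidationError(f"gene {gene} is unmapped; degeneracy undefined")
    return int(get_evaluator(instance).degeneracy(chromosome)[gene])


def objective_vector(instance: ProblemInstance, chromosome: Chromosome) -> ObjectiveVector:
    """The four minimization objectives F1..F4 of a chromosome."""
    return get_evaluator(instance).evaluate(chromosome)[0]


def global_score_G(
    instance: ProblemInstance,
    chromosome: Chromosome,
    config: Optional[ScoringConfig] = None,
) -> float:
    """The aggregated global score G ∈ [0, 1] of a chromosome."""
    return get_evaluator(instance, config).evaluate(chromosome)[1]


def chromosome_shift_list(instance: ProblemInstance, chromosome: Chromosome):
    """Shift list implied by a chromosome: per atom δ̄(a) and the contribution sd."""
    from .peak_io import ShiftList

    table = project_atom_shifts(instance, chromosome)
    entries = {}
    for atom, rows in table.contributions.items():
        values = [v for *_, v in rows]
        mean = table.mean_shift[atom]
        sd = float(np.std(values)) if len(values) > 1 else 0.0
        entries[atom] = (mean, sd)
    return ShiftList(entries=entries)
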