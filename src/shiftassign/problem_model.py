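"""The combinatorial assignment problem and its chromosome encoding.

An assignment candidate maps every expected peak either to a measured peak of
the same spectrum or to nothing.  Chromosomes are plain integer numpy arrays
with one gene per expected peak, in the deterministic global order obtained by
concatenating the per-spectrum expected lists in the given spectrum order.  A
gene holds the 0-based index of a measured peak within its own spectrum, or
``NONE`` (serialized as -1) for an unassigned expected peak.  Mapping only
within the same spectrum and at most once per expected peak is therefore
guaranteed by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .peak_io import (
    AtomId,
    ExpectedPeak,
    MeasuredPeak,
    SequenceRecord,
    ShiftStatistics,
    SpectrumDefinition,
    ValidationError,
)

#: Gene value marking an unassigned expected peak.
NONE = -1

Chromosome = np.ndarray


@dataclass(frozen=True)
class ToleranceConfig:
    """Per-nucleus experimental ppm tolerances (peak-position accuracy)."""

    h: float = 0.03
    c: float = 0.4
    n: float = 0.4

    def __post_init__(self) -> None:
        if min(self.h, self.c, self.n) <= 0:
            raise ValidationError("tolerances must be positive")

    def for_nucleus(self, nucleus: str) -> float:
        try:
            return {"H": self.h, "C": self.c, "N": self.n}[nucleus.upper()]
        except KeyError:
            raise ValidationError(f"unknown nucleus {nucleus!r}") from None

    def for_atom(self, atom: AtomId) -> float:
        return self.for_nucleus(atom.nucleus)


class ProblemInstance:
    """An assignment problem: sequence, spectra, peaks, statistics, tolerances.

    Beyond holding the inputs, the instance precomputes the gene table (the
    bijection between global gene indices and (spectrum, expected peak)), the
    deduplicated atom registry shared across spectra, and numpy views of the
    measured-peak positions that the scoring and initialization code relies
    on.
    """

    def __init__(
        self,
        sequence: SequenceRecord,
        spectra: Sequence[SpectrumDefinition],
        expected: dict[str, Sequence[ExpectedPeak]],
        measured: dict[str, Sequence[MeasuredPeak]],
        statistics: ShiftStatistics,
        tolerances: ToleranceConfig = ToleranceConfig(),
    ):
        self.sequence = sequence
        self.spectra = list(spectra)
        self.statistics = statistics
        self.tolerances = tolerances
        names = [s.name for s in self.spectra]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate spectrum names")
        for key in expected:
            if key not in names:
                raise ValidationError(f"expected peaks reference unknown spectrum {key!r}")
        for key in measured:
            if key not in names:
                raise ValidationError(f"measured peaks reference unknown spectrum {key!r}")
        self.expected = {s.name: list(expected.get(s.name, ())) for s in self.spectra}
        self.measured = {s.name: list(measured.get(s.name, ())) for s in self.spectra}

        # gene table: global gene index -> (spectrum index, expected peak)
        self.genes: list[tuple[int, ExpectedPeak]] = []
        for si, spec in enumerate(self.spectra):
            for peak in self.expected[spec.name]:
                if len(peak.atoms) != spec.ndim:
                    raise ValidationError(
                        f"expected peak {peak.peak_id} of {spec.name!r} has "
                        f"{len(peak.atoms)} atoms for {spec.ndim} dimensions"
                    )
                self.genes.append((si, peak))
        self.L = len(self.genes)

        # atom registry (sorted for determinism) with per-atom nucleus checks
        nucleus_of: dict[AtomId, str] = {}
        for si, peak in self.genes:
            spec = self.spectra[si]
            for d, atom in enumerate(peak.atoms):
                nuc = spec.dimensions[d][1]
                prev = nucleus_of.setdefault(atom, nuc)
                if prev != nuc:
                    raise ValidationError(
                        f"atom {atom} appears on both {prev} and {nuc} axes"
                    )
        self.atoms: list[AtomId] = sorted(nucleus_of)
        self.atom_index = {a: i for i, a in enumerate(self.atoms)}
        self.atom_nucleus = {a: nucleus_of[a] for a in self.atoms}
        for atom in self.atoms:
            if atom.residue_number not in sequence:
                raise ValidationError(
                    f"atom {atom} references a residue absent from the sequence"
                )

        # numpy views used by scoring / initialization
        self.measured_positions: list[np.ndarray] = []
        self.measured_counts = np.zeros(len(self.spectra), dtype=np.int64)
        for si, spec in enumerate(self.spectra):
            peaks = self.measured[spec.name]
            pos = np.array([p.position for p in peaks], dtype=float).reshape(
                len(peaks), spec.ndim
            )
            self.measured_positions.append(pos)
            self.measured_counts[si] = len(peaks)

        self.gene_spectrum = np.array([si for si, _ in self.genes], dtype=np.int64)
        self.gene_measured_count = self.measured_counts[self.gene_spectrum] if self.L else np.zeros(0, dtype=np.int64)
        # per-gene atom indices, aligned with spectrum dimensions
        self.gene_atoms: list[np.ndarray] = [
            np.array([self.atom_index[a] for a in peak.atoms], dtype=np.int64)
            for _, peak in self.genes
        ]

        # per-atom tolerance and statistics arrays (nan = no statistics entry)
        n_atoms = len(self.atoms)
        self.atom_tol = np.array(
            [tolerances.for_nucleus(self.atom_nucleus[a]) for a in self.atoms]
        ) if n_atoms else np.zeros(0)
        self.atom_mu = np.full(n_atoms, np.nan)
        self.atom_sigma = np.full(n_atoms, np.nan)
        for i, atom in enumerate(self.atoms):
            rtype = sequence.residue_type(atom.residue_number)
            if (rtype, atom.name) in statistics:
                mu, sigma = statistics.get(rtype, atom.name)
                self.atom_mu[i] = mu
                self.atom_sigma[i] = sigma

        self._evaluators: dict = {}

    # -- convenience ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        """|A0|: number of distinct atoms occurring in any expected peak."""
        return len(self.atoms)

    def residue_type_of(self, atom: AtomId) -> str:
        return self.sequence.residue_type(atom.residue_number)

    def spectrum_of_gene(self, gene: int) -> SpectrumDefinition:
        return self.spectra[self.gene_spectrum[gene]]

    def empty_chromosome(self) -> Chromosome:
        return np.full(self.L, NONE, dtype=np.int64)

    def random_chromosome(self, rng: np.random.Generator) -> Chromosome:
        """Uniform chromosome: each gene uniform over {NONE} ∪ measured indices."""
        return rng.integers(-1, self.gene_measured_count, dtype=np.int64, endpoint=False)


def build_instance(
    sequence: SequenceRecord,
    spectra: Sequence[SpectrumDefinition],
    expected: dict[str, Sequence[ExpectedPeak]],
    measured: dict[str, Sequence[MeasuredPeak]],
    statistics: ShiftStatistics,
    tolerances: ToleranceConfig = ToleranceConfig(),
) -> ProblemInstance:
    """Assemble a :class:`ProblemInstance` from parsed inputs."""
    return ProblemInstance(sequence, spectra, expected, measured, statistics, tolerances)


@dataclass
class AtomShiftTable:
    """Chemical-shift contributions per atom implied by a chromosome.

    ``contributions[a]`` lists ``(spectrum name, expected peak id, dimension,
    ppm)`` tuples from every mapped expected peak touching atom ``a``;
    ``mean_shift[a]`` is their arithmetic mean.  Atoms with no contribution
    are unassigned (``a ∈ A`` iff it has contributions).
    """

    contributions: dict[AtomId, list[tuple[str, int, int, float]]]
    mean_shift: dict[AtomId, float]

    @property
    def assigned_atoms(self) -> set[AtomId]:
        return set(self.contributions)


def project_atom_shifts(instance: ProblemInstance, chromosome: Chromosome) -> AtomShiftTable:
    """Project a chromosome onto per-atom chemical-shift contributions."""
    contributions: dict[AtomId, list[tuple[str, int, int, float]]] = {}
    for g, (si, peak) in enumerate(instance.genes):
        m = int(chromosome[g])
        if m == NONE:
            continue
        spec = instance.spectra[si]
        pos = instance.measured_positions[si][m]
        for d, atom in enumerate(peak.atoms):
            contributions.setdefault(atom, []).append(
                (spec.name, peak.peak_id, d, float(pos[d]))
            )
    mean_shift = {
        atom: math.fsum(v for *_, v in rows) / len(rows)
        for atom, rows in contributions.items()
    }
    return AtomShiftTable(contributions=contributions, mean_shift=mean_shift)


def validate_chromosome(instance: ProblemInstance, chromosome: Chromosome) -> list[str]:
    """Return violation messages; empty iff every gene is NONE or a valid
    same-spectrum measured index.  The spread-vs-tolerance condition is not
    checked here: it is absorbed into the alignment objective."""
    violations: list[str] = []
    chromosome = np.asarray(chromosome)
    if chromosome.shape != (instance.L,):
        return [f"chromosome length {chromosome.shape} != ({instance.L},)"]
    for g in range(instance.L):
        v = int(chromosome[g])
        limit = int(instance.gene_measured_count[g])
        if v == NONE:
            continue
        if not 0 <= v < limit:
            violations.append(
                f"gene {g}: value {v} outside [0, {limit}) for spectrum "
                f"{instance.spectrum_of_gene(g).name!r}"
            )
    return violations


def log10_search_space(instance: ProblemInstance) -> float:
    """log10 of the number of full-mapping candidates, Σ_s E_s·log10(M_s).

    This follows the convention that counts one choice per expected peak among
    the measured peaks of its spectrum (the unassigned option is excluded);
    spectra without measured peaks contribute 0.
    """
    total = 0.0
    for si, spec in enumerate(instance.spectra):
        e = len(instance.expected[spec.name])
        m = int(instance.measured_counts[si])
        if e > 0 and m > 0:
            total += e * math.log10(m)
    return total


# ---------------------------------------------------------------------------
# Chromosome serialization (one line per spectrum)
# ---------------------------------------------------------------------------


def serialize_chromosome(instance: ProblemInstance, chromosome: Chromosome) -> str:
    lines = []
    offset = 0
    for spec in instance.spectra:
        count = len(instance.expected[spec.name])
        genes = chromosome[offset : offset + count]
        lines.append(spec.name + " " + " ".join(str(int(v)) for v in genes))
        offset += count
    return "\n".join(lines) + "\n"


def parse_chromosome(instance: ProblemInstance, text: str) -> Chromosome:
    values: dict[str, list[int]] = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        values[parts[0]] = [int(v) for v in parts[1:]]
    chromosome = []
    for spec in instance.spectra:
        genes = values.get(spec.name, [])
        if len(genes) != len(instance.expected[spec.name]):
            raise ValidationError(
                f"spectrum {spec.name!r}: {len(genes)} genes for "
                f"{len(instance.expected[spec.name])} expected peaks"
            )
        chromosome.extend(genes)
    arr = np.array(chromosome, dtype=np.int64)
    problems = validate_chromosome(instance, arr)
    if problems:
        raise ValidationError("; ".join(problems))
    return arr


def write_chromosome(instance: ProblemInstance, chromosome: Chromosome, path) -> None:
    from pathlib import Path

    Path(path).write_text(serialize_chromosome(instance, chromosome))


def read_chromosome(instance: ProblemInstance, path) -> Chromosome:
    from pathlib import Path

    return parse_chromosome(instance, Path(path).read_text())
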