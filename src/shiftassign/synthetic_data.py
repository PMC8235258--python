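"""Synthetic assignment problems with known ground truth.

The generator emulates the regime that makes real triple-resonance data hard:
every atom gets a true shift drawn from its statistics entry, expected peaks
are enumerated from simplified spectrum templates, and measured lists are
degraded — only a fraction of expected peaks is observed (about half in
difficult real data), positions carry per-nucleus Gaussian noise, and
artifact peaks (up to one per real peak in bad spectra) are scattered
uniformly over each spectrum's occupied ppm bounding box.  Peak ids are
shuffled so file order carries no information.  The true expected→measured
mapping and the true shifts are recorded for evaluation.

Templates are data: each names its dimensions and the atom/residue-offset
patterns that produce an expected peak, so the built-in simplified set
(N15HSQC, HNCA, HNCO, CBCANH, C13HSQC) can be extended by users.  An atom
pattern is skipped when the residue lacks the atom (no amide H on prolines or
on the first residue; no CB/HB on glycine).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .peak_io import (
    AtomId,
    ExpectedPeak,
    MeasuredPeak,
    SequenceRecord,
    ShiftList,
    ShiftStatistics,
    SpectrumDefinition,
    ValidationError,
    default_statistics,
)
from .problem_model import (
    NONE,
    Chromosome,
    ProblemInstance,
    ToleranceConfig,
    build_instance,
)

AMINO_ACIDS_NO_PRO = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass(frozen=True)
class SpectrumTemplate:
    """A spectrum type plus the atom patterns that generate expected peaks.

    Each pattern lists, per dimension, an (atom name, residue offset) pair;
    the pattern is instantiated at every anchor residue where all atoms
    exist.
    """

    name: str
    dimensions: tuple[tuple[str, str], ...]
    patterns: tuple[tuple[tuple[str, int], ...], ...]

    def definition(self) -> SpectrumDefinition:
        return SpectrumDefinition(name=self.name, dimensions=self.dimensions)


BUILTIN_TEMPLATES: dict[str, SpectrumTemplate] = {
    t.name: t
    for t in (
        SpectrumTemplate(
            name="N15HSQC",
            dimensions=(("HN", "H"), ("N15", "N")),
            patterns=((("H", 0), ("N", 0)),),
        ),
        SpectrumTemplate(
            name="HNCA",
            dimensions=(("HN", "H"), ("N15", "N"), ("C13", "C")),
            patterns=(
                (("H", 0), ("N", 0), ("CA", 0)),
                (("H", 0), ("N", 0), ("CA", -1)),
            ),
        ),
        SpectrumTemplate(
            name="HNCO",
            dimensions=(("HN", "H"), ("N15", "N"), ("C13", "C")),
            patterns=((("H", 0), ("N", 0), ("C", -1)),),
        ),
        SpectrumTemplate(
            name="CBCANH",
            dimensions=(("HN", "H"), ("N15", "N"), ("C13", "C")),
            patterns=(
                (("H", 0), ("N", 0), ("CA", 0)),
                (("H", 0), ("N", 0), ("CB", 0)),
                (("H", 0), ("N", 0), ("CA", -1)),
                (("H", 0), ("N", 0), ("CB", -1)),
            ),
        ),
        SpectrumTemplate(
            name="C13HSQC",
            dimensions=(("H1", "H"), ("C13", "C")),
            patterns=(
                (("HA", 0), ("CA", 0)),
                (("HB", 0), ("CB", 0)),
            ),
        ),
    )
}

DEFAULT_TEMPLATE_NAMES = ("N15HSQC", "HNCA", "HNCO", "CBCANH", "C13HSQC")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic dataset.

    Defaults emulate difficult real spectra: half the expected peaks
    unobservable and as many artifact peaks as real ones; coordinate noise
    defaults to a third of each nucleus tolerance.
    """

    sequence: Optional[SequenceRecord] = None
    sequence_length: int = 20
    template_names: tuple[str, ...] = DEFAULT_TEMPLATE_NAMES
    templates: Optional[tuple[SpectrumTemplate, ...]] = None
    noise_sd: Optional[dict[str, float]] = None
    p_missing: float = 0.5
    artifact_ratio: float = 1.0
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_missing <= 1.0:
            raise ValidationError("p_missing must lie in [0, 1]")
        if self.artifact_ratio < 0:
            raise ValidationError("artifact_ratio must be >= 0")

    def resolve_templates(self) -> tuple[SpectrumTemplate, ...]:
        if self.templates is not None:
            return self.templates
        return tuple(BUILTIN_TEMPLATES[name] for name in self.template_names)

    def resolve_noise(self) -> dict[str, float]:
        if self.noise_sd is not None:
            return dict(self.noise_sd)
        t = self.tolerances
        return {"H": t.h / 3.0, "C": t.c / 3.0, "N": t.n / 3.0}


@dataclass
class GroundTruth:
    """What the generator knows: true shifts and the true peak mapping."""

    shifts: dict[AtomId, float]
    #: (spectrum name, expected peak id) -> measured peak id, or None if unobserved
    mapping: dict[tuple[str, int], Optional[int]]
    reference: ShiftList

    def chromosome(self, instance: ProblemInstance) -> Chromosome:
        """The true assignment as a chromosome over ``instance``."""
        measured_index: dict[tuple[str, int], int] = {}
        for spec in instance.spectra:
            for idx, peak in enumerate(instance.measured[spec.name]):
                measured_index[(spec.name, peak.peak_id)] = idx
        chrom = instance.empty_chromosome()
        for g, (si, peak) in enumerate(instance.genes):
            name = instance.spectra[si].name
            target = self.mapping.get((name, peak.peak_id))
            if target is not None:
                chrom[g] = measured_index[(name, target)]
        return chrom


def random_sequence(length: int, rng: np.random.Generator) -> SequenceRecord:
    """A random sequence over the 19 non-proline standard residue types.

    Prolines are excluded so that every residue past the first carries an
    amide and anchors the HN-rooted templates.
    """
    types = [AMINO_ACIDS_NO_PRO[int(i)] for i in rng.integers(len(AMINO_ACIDS_NO_PRO), size=length)]
    return SequenceRecord(residues=tuple((i + 1, t) for i, t in enumerate(types)))


def _atom_exists(sequence: SequenceRecord, number: int, name: str) -> bool:
    if number not in sequence:
        return False
    rtype = sequence.residue_type(number)
    if name == "H":
        return rtype != "PRO" and number != sequence.numbers[0]
    if name in ("CB", "HB"):
        return rtype != "GLY"
    return True


def generate_expected_peaks(
    sequence: SequenceRecord, templates: Sequence[SpectrumTemplate]
) -> dict[str, list[ExpectedPeak]]:
    """Enumerate template instantiations over the sequence, deterministically."""
    expected: dict[str, list[ExpectedPeak]] = {}
    for template in templates:
        peaks: list[ExpectedPeak] = []
        next_id = 1
        for number, _ in sequence:
            for pattern in template.patterns:
                atoms = []
                ok = True
                for name, offset in pattern:
                    target = number + offset
                    if not _atom_exists(sequence, target, name):
                        ok = False
                        break
                    atoms.append(AtomId(name=name, residue_number=target))
                if ok:
                    peaks.append(
                        ExpectedPeak(
                            peak_id=next_id, spectrum=template.name, atoms=tuple(atoms)
                        )
                    )
                    next_id += 1
        expected[template.name] = peaks
    return expected


def sample_true_shifts(
    sequence: SequenceRecord,
    statistics: ShiftStatistics,
    rng: np.random.Generator,
    atoms: Sequence[AtomId],
) -> dict[AtomId, float]:
    """Independent true shifts ~ Normal(μ, σ) from the statistics table."""
    shifts: dict[AtomId, float] = {}
    for atom in sorted(atoms):
        rtype = sequence.residue_type(atom.residue_number)
        mu, sigma = statistics.get(rtype, atom.name)
        shifts[atom] = float(rng.normal(mu, sigma))
    return shifts


def generate_measured_peaks(
    truth_shifts: dict[AtomId, float],
    expected: dict[str, list[ExpectedPeak]],
    templates: Sequence[SpectrumTemplate],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[MeasuredPeak]], dict[tuple[str, int], Optional[int]]]:
    """Observe expected peaks with noise, drop some, add artifacts, shuffle ids."""
    noise = config.resolve_noise()
    measured: dict[str, list[MeasuredPeak]] = {}
    mapping: dict[tuple[str, int], Optional[int]] = {}
    for template in templates:
        name = template.name
        nuclei = [nuc for _, nuc in template.dimensions]
        real: list[tuple[int, tuple[float, ...]]] = []  # (expected id, position)
        for peak in expected[name]:
            mapping[(name, peak.peak_id)] = None
            if rng.random() < config.p_missing:
                continue
            position = tuple(
                truth_shifts[atom] + rng.normal(0.0, noise[nuc]) if noise[nuc] > 0
                else truth_shifts[atom]
                for atom, nuc in zip(peak.atoms, nuclei)
            )
            real.append((peak.peak_id, position))
        positions = [pos for _, pos in real]
        n_artifacts = math.floor(config.artifact_ratio * len(real))
        artifact_positions: list[tuple[float, ...]] = []
        if n_artifacts and positions:
            arr = np.array(positions)
            lo = arr.min(axis=0)
            hi = arr.max(axis=0)
            for _ in range(n_artifacts):
                artifact_positions.append(
                    tuple(float(rng.uniform(l, h)) for l, h in zip(lo, hi))
                )
        entries: list[tuple[Optional[int], tuple[float, ...]]] = [
            (eid, pos) for eid, pos in real
        ] + [(None, pos) for pos in artifact_positions]
        order = rng.permutation(len(entries))
        peaks: list[MeasuredPeak] = []
        for new_id, idx in enumerate(order, start=1):
            eid, pos = entries[int(idx)]
            peaks.append(MeasuredPeak(peak_id=new_id, spectrum=name, position=pos))
            if eid is not None:
                mapping[(name, eid)] = new_id
        measured[name] = peaks
    return measured, mapping


def make_dataset(
    config: SimulationConfig = SimulationConfig(),
    statistics: Optional[ShiftStatistics] = None,
) -> tuple[ProblemInstance, GroundTruth]:
    """Compose sequence, true shifts, expected and measured peaks into a problem."""
    rng = np.random.default_rng(config.seed)
    statistics = statistics or default_statistics()
    sequence = config.sequence or random_sequence(config.sequence_length, rng)
    templates = config.resolve_templates()
    expected = generate_expected_peaks(sequence, templates)
    atoms = sorted({a for peaks in expected.values() for p in peaks for a in p.atoms})
    shifts = sample_true_shifts(sequence, statistics, rng, atoms)
    measured, mapping = generate_measured_peaks(shifts, expected, templates, config, rng)
    instance = build_instance(
        sequence=sequence,
        spectra=[t.definition() for t in templates],
        expected=expected,
        measured=measured,
        statistics=statistics,
        tolerances=config.tolerances,
    )
    reference = ShiftList(entries={a: (shifts[a], None) for a in atoms})
    truth = GroundTruth(shifts=shifts, mapping=mapping, reference=reference)
    return instance, truth


def write_dataset(
    instance: ProblemInstance, truth: GroundTruth, directory, prefix: str = "synthetic"
) -> None:
    """Write the dataset in all peak_io formats plus a JSON ground-truth map."""
    from . import peak_io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    peak_io.write_sequence(instance.sequence, directory / f"{prefix}.seq")
    for spec in instance.spectra:
        peak_io.write_expected_peaks(
            instance.expected[spec.name], spec, directory / f"{prefix}_{spec.name}.expected"
        )
        peak_io.write_xeasy_peaks(
            instance.measured[spec.name], spec, directory / f"{prefix}_{spec.name}.peaks"
        )
    peak_io.write_shift_list(truth.reference, directory / f"{prefix}_reference.prot")
    payload = {
        f"{name}:{eid}": mid for (name, eid), mid in sorted(truth.mapping.items())
    }
    (directory / f"{prefix}_truth.json").write_text(json.dumps(payload, indent=1))
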