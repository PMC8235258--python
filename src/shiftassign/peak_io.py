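"""Readers and writers for assignment-problem input files.

The formats are deliberately small, line-oriented text dialects:

* sequence files (``.seq``): one ``TYPE NUMBER`` pair per line;
* measured peak lists (``.peaks``): the XEASY peak-list dialect;
* expected peak lists (``.expected``): peak id followed by one atom
  identifier per spectral dimension;
* chemical-shift lists (``.prot``): XEASY-prot-style
  ``index shift sd atomName residueNumber`` lines;
* shift-statistics tables (``.stats``): ``residue_type atom_name mu sigma``.

Atom identifiers are written ``atomName.residueNumber`` with 1-based residue
numbers taken from the sequence file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

PathLike = Union[str, Path]

STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


class FormatError(ValueError):
    """A file does not conform to its dialect (reported with 1-based line numbers)."""


class ValidationError(ValueError):
    """Parsed content violates a semantic invariant."""


class MissingStatisticsError(KeyError):
    """No statistics entry exists for a (residue type, atom name) pair."""


# ---------------------------------------------------------------------------
# Atoms and sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class AtomId:
    """An atom within the molecule, keyed by name and 1-based residue number."""

    name: str
    residue_number: int

    def __str__(self) -> str:
        return f"{self.name}.{self.residue_number}"

    @property
    def nucleus(self) -> str:
        """Nucleus type inferred from the leading letter of the atom name."""
        first = self.name[0].upper()
        if first in ("H", "Q"):
            return "H"
        if first in ("C", "N"):
            return first
        raise ValidationError(f"cannot infer nucleus for atom name {self.name!r}")

    @classmethod
    def parse(cls, token: str) -> "AtomId":
        name, sep, num = token.rpartition(".")
        if not sep or not name:
            raise FormatError(f"atom identifier {token!r} is not 'name.residue'")
        try:
            residue = int(num)
        except ValueError as exc:
            raise FormatError(f"atom identifier {token!r}: bad residue number") from exc
        return cls(name=name, residue_number=residue)


@dataclass(frozen=True)
class SequenceRecord:
    """The protein sequence with its residue numbering."""

    residues: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        numbers = [n for n, _ in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValidationError("residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[tuple[int, str]]:
        return iter(self.residues)

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(n for n, _ in self.residues)

    def residue_type(self, number: int) -> str:
        for n, t in self.residues:
            if n == number:
                return t
        raise KeyError(f"no residue numbered {number}")

    def __contains__(self, number: int) -> bool:
        return any(n == number for n, _ in self.residues)


def read_sequence(
    path: PathLike, extra_residue_types: Iterable[str] = ()
) -> SequenceRecord:
    """Read a ``TYPE NUMBER`` sequence file ('#' lines are comments)."""
    allowed = STANDARD_AMINO_ACIDS | {t.upper() for t in extra_residue_types}
    residues: list[tuple[int, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'TYPE NUMBER', got {stripped!r}")
        rtype = parts[0].upper()
        if rtype not in allowed:
            raise FormatError(f"{path}:{lineno}: unknown residue type {parts[0]!r}")
        try:
            number = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad residue number {parts[1]!r}") from exc
        residues.append((number, rtype))
    if not residues:
        raise ValidationError(f"{path}: no residues")
    return SequenceRecord(residues=tuple(residues))


def write_sequence(sequence: SequenceRecord, path: PathLike) -> None:
    lines = [f"{rtype} {number}" for number, rtype in sequence]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Spectra and peaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumDefinition:
    """A spectrum type: its name and ordered (axis label, nucleus) dimensions."""

    name: str
    dimensions: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.dimensions) <= 4:
            raise ValidationError(
                f"spectrum {self.name!r}: {len(self.dimensions)} dimensions (need 2-4)"
            )
        for _, nucleus in self.dimensions:
            if nucleus not in ("H", "C", "N"):
                raise ValidationError(
                    f"spectrum {self.name!r}: nucleus {nucleus!r} not in H/C/N"
                )

    @property
    def ndim(self) -> int:
        return len(self.dimensions)


@dataclass(frozen=True)
class MeasuredPeak:
    """A picked peak: known ppm position, unknown atoms."""

    peak_id: int
    spectrum: str
    position: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(math.isfinite(p) for p in self.position):
            raise ValidationError(f"peak {self.peak_id}: non-finite ppm coordinate")


@dataclass(frozen=True)
class ExpectedPeak:
    """A predicted peak: known atoms, unknown position."""

    peak_id: int
    spectrum: str
    atoms: tuple[AtomId, ...]


def read_xeasy_peaks(path: PathLike, spec: SpectrumDefinition) -> list[MeasuredPeak]:
    """Read an XEASY peak list.

    Header lines start with '#'; data lines are the peak id, one ppm value per
    dimension, then trailing columns (colour, volume, assignment) that are
    ignored.  The dimension count declared in the header, when present, and
    the per-line coordinate count must match ``spec``.
    """
    ndim = spec.ndim
    peaks: list[MeasuredPeak] = []
    seen: set[int] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            tokens = stripped.lstrip("#").split()
            if "dimensions" in [t.lower() for t in tokens]:
                declared = next((t for t in tokens if t.isdigit()), None)
                if declared is not None and int(declared) != ndim:
                    raise FormatError(
                        f"{path}:{lineno}: file declares {declared} dimensions, "
                        f"spectrum {spec.name!r} has {ndim}"
                    )
            continue
        parts = stripped.split()
        if len(parts) < 1 + ndim:
            raise FormatError(
                f"{path}:{lineno}: expected id + {ndim} coordinates, got {stripped!r}"
            )
        try:
            peak_id = int(parts[0])
            coords = tuple(float(x) for x in parts[1 : 1 + ndim])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparsable coordinate") from exc
        if peak_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate peak id {peak_id}")
        seen.add(peak_id)
        peaks.append(MeasuredPeak(peak_id=peak_id, spectrum=spec.name, position=coords))
    return peaks


def write_xeasy_peaks(peaks: Iterable[MeasuredPeak], spec: SpectrumDefinition, path: PathLike) -> None:
    lines = [f"# Number of dimensions {spec.ndim}"]
    for i, (label, _) in enumerate(spec.dimensions, start=1):
        lines.append(f"#INAME {i} {label}")
    for peak in peaks:
        coords = " ".join(f"{p:9.3f}" for p in peak.position)
        trailing = "1 U 1.000e+00 0.000e+00 e 0" + " 0" * spec.ndim
        lines.append(f"{peak.peak_id:4d} {coords} {trailing}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_expected_peaks(
    path: PathLike,
    spec: SpectrumDefinition,
    sequence: Optional[SequenceRecord] = None,
) -> list[ExpectedPeak]:
    """Read an expected-peak list: ``id atom1 atom2 ...`` lines, one atom per
    dimension.  When ``sequence`` is given, every atom's residue number must
    occur in it."""
    ndim = spec.ndim
    peaks: list[ExpectedPeak] = []
    seen: set[int] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 1 + ndim:
            raise FormatError(
                f"{path}:{lineno}: expected id + {ndim} atoms, got {stripped!r}"
            )
        try:
            peak_id = int(parts[0])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad peak id {parts[0]!r}") from exc
        if peak_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate peak id {peak_id}")
        seen.add(peak_id)
        atoms = tuple(AtomId.parse(tok) for tok in parts[1:])
        if sequence is not None:
            for atom in atoms:
                if atom.residue_number not in sequence:
                    raise ValidationError(
                        f"{path}:{lineno}: atom {atom} references a residue "
                        "absent from the sequence"
                    )
        peaks.append(ExpectedPeak(peak_id=peak_id, spectrum=spec.name, atoms=atoms))
    return peaks


def write_expected_peaks(peaks: Iterable[ExpectedPeak], spec: SpectrumDefinition, path: PathLike) -> None:
    lines = [f"# expected peaks for {spec.name} ({spec.ndim} dimensions)"]
    for peak in peaks:
        atoms = " ".join(str(a) for a in peak.atoms)
        lines.append(f"{peak.peak_id} {atoms}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Shift lists
# ---------------------------------------------------------------------------


@dataclass
class ShiftList:
    """Chemical-shift values assigned to atoms: atom -> (shift ppm, sd ppm or None)."""

    entries: dict[AtomId, tuple[float, Optional[float]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, atom: AtomId) -> bool:
        return atom in self.entries

    def shift(self, atom: AtomId) -> float:
        return self.entries[atom][0]


def write_shift_list(shifts: ShiftList, path: PathLike) -> None:
    """Write an XEASY-prot-style shift list: ``index shift sd atomName residueNumber``."""
    lines = ["# index shift sd atom residue"]
    ordered = sorted(shifts.entries.items(), key=lambda kv: (kv[0].residue_number, kv[0].name))
    for index, (atom, (shift, sd)) in enumerate(ordered, start=1):
        sd_txt = f"{sd:.3f}" if sd is not None else "0.000"
        lines.append(f"{index:4d} {shift:9.3f} {sd_txt} {atom.name} {atom.residue_number}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_shift_list(path: PathLike) -> ShiftList:
    entries: dict[AtomId, tuple[float, Optional[float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 5:
            raise FormatError(
                f"{path}:{lineno}: expected 'index shift sd atom residue', got {stripped!r}"
            )
        try:
            shift = float(parts[1])
            sd = float(parts[2])
            atom = AtomId(name=parts[3], residue_number=int(parts[4]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparsable field") from exc
        if atom in entries:
            raise ValidationError(f"{path}:{lineno}: duplicate atom {atom}")
        entries[atom] = (shift, sd)
    return ShiftList(entries=entries)


# ---------------------------------------------------------------------------
# Shift statistics
# ---------------------------------------------------------------------------


class ShiftStatistics:
    """Per (residue type, atom name) chemical-shift mean and standard deviation.

    Lookups for pairs without an entry raise :class:`MissingStatisticsError`
    rather than returning a silent default.
    """

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float]]):
        for (rtype, aname), (_, sigma) in entries.items():
            if sigma <= 0:
                raise ValidationError(
                    f"statistics for ({rtype}, {aname}): sigma must be > 0"
                )
        self.entries = dict(entries)

    def get(self, residue_type: str, atom_name: str) -> tuple[float, float]:
        try:
            return self.entries[(residue_type.upper(), atom_name.upper())]
        except KeyError:
            raise MissingStatisticsError(
                f"no statistics for ({residue_type}, {atom_name})"
            ) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        rtype, aname = key
        return (rtype.upper(), aname.upper()) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_shift_statistics(path: PathLike) -> ShiftStatistics:
    """Read a ``residue_type atom_name mu sigma`` table."""
    entries: dict[tuple[str, str], tuple[float, float]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 4:
            raise FormatError(
                f"{path}:{lineno}: expected 'residue atom mu sigma', got {stripped!r}"
            )
        try:
            mu, sigma = float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparsable number") from exc
        if sigma <= 0:
            raise ValidationError(f"{path}:{lineno}: sigma must be > 0, got {sigma}")
        entries[(parts[0].upper(), parts[1].upper())] = (mu, sigma)
    return ShiftStatistics(entries)


def default_statistics() -> ShiftStatistics:
    """The shift-statistics table shipped with the package."""
    ref = resources.files("shiftassign.data").joinpath("shift_statistics.tsv")
    with resources.as_file(ref) as path:
        return read_shift_statistics(path)
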