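import numpy as np
import pytest
from hypothesis import settings

from shiftassign.peak_io import (
    AtomId,
    ExpectedPeak,
    MeasuredPeak,
    SequenceRecord,
    ShiftStatistics,
    SpectrumDefinition,
)
from shiftassign.problem_model import ToleranceConfig, build_instance

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def stats_small():
    return ShiftStatistics(
        {
            ("ALA", "H"): (8.0, 0.5),
            ("ALA", "N"): (120.0, 3.0),
            ("ALA", "CA"): (53.0, 2.0),
            ("GLY", "H"): (8.3, 0.5),
            ("GLY", "N"): (110.0, 3.0),
            ("GLY", "CA"): (45.0, 1.5),
        }
    )


@pytest.fixture
def two_residue_sequence():
    return SequenceRecord(residues=((1, "ALA"), (2, "GLY")))


def _hsqc():
    return SpectrumDefinition(name="HSQC", dimensions=(("HN", "H"), ("N15", "N")))


def _hnca():
    return SpectrumDefinition(
        name="HNCA", dimensions=(("HN", "H"), ("N15", "N"), ("C13", "C"))
    )


@pytest.fixture
def tiny_instance(two_residue_sequence, stats_small):
    """2 spectra, 3 expected peaks, hand-placed measured peaks at the means."""
    hsqc, hnca = _hsqc(), _hnca()
    expected = {
        "HSQC": [
            ExpectedPeak(1, "HSQC", (AtomId("H", 1), AtomId("N", 1))),
            ExpectedPeak(2, "HSQC", (AtomId("H", 2), AtomId("N", 2))),
        ],
        "HNCA": [
            ExpectedPeak(1, "HNCA", (AtomId("H", 2), AtomId("N", 2), AtomId("CA", 1))),
        ],
    }
    measured = {
        "HSQC": [
            MeasuredPeak(1, "HSQC", (8.0, 120.0)),
            MeasuredPeak(2, "HSQC", (8.3, 110.0)),
        ],
        "HNCA": [MeasuredPeak(1, "HNCA", (8.3, 110.0, 53.0))],
    }
    return build_instance(
        two_residue_sequence, [hsqc, hnca], expected, measured, stats_small
    )


@pytest.fixture
def one_gene_instance(stats_small):
    """A single 2D expected peak with two measured candidates (one at the means)."""
    sequence = SequenceRecord(residues=((1, "ALA"),))
    hsqc = _hsqc()
    expected = {
        "HSQC": [ExpectedPeak(1, "HSQC", (AtomId("H", 1), AtomId("N", 1)))]
    }
    measured = {
        "HSQC": [
            MeasuredPeak(1, "HSQC", (9.9, 135.0)),  # far from the ALA statistics
            MeasuredPeak(2, "HSQC", (8.0, 120.0)),  # exactly at the means
        ]
    }
    return build_instance(sequence, [hsqc], expected, measured, stats_small)


def random_tiny_instance(rng: np.random.Generator, max_expected=10, max_measured=5):
    """A small random instance for oracle-equivalence fuzzing."""
    n_res = int(rng.integers(2, 5))
    types = ["ALA", "GLY"]
    sequence = SequenceRecord(
        residues=tuple(
            (i + 1, types[int(rng.integers(2))]) for i in range(n_res)
        )
    )
    stats = ShiftStatistics(
        {
            (t, a): (mu + float(rng.normal(0, 0.2)), sd)
            for t in types
            for a, mu, sd in (
                ("H", 8.1, 0.5),
                ("N", 118.0, 4.0),
                ("CA", 50.0, 3.0),
            )
        }
    )
    n_spectra = int(rng.integers(1, 3))
    spectra, expected, measured = [], {}, {}
    total_expected = 0
    for s in range(n_spectra):
        ndim = int(rng.integers(2, 4))
        dims = tuple(
            (f"d{d}", ("H", "N", "C")[int(rng.integers(3))]) for d in range(ndim)
        )
        spec = SpectrumDefinition(name=f"S{s}", dimensions=dims)
        spectra.append(spec)
        n_exp = int(rng.integers(1, max(2, max_expected // n_spectra + 1)))
        n_exp = min(n_exp, max_expected - total_expected)
        total_expected += n_exp
        names = {"H": "H", "N": "N", "C": "CA"}
        expected[spec.name] = [
            ExpectedPeak(
                peak_id=k + 1,
                spectrum=spec.name,
                atoms=tuple(
                    AtomId(names[nuc], int(rng.integers(1, n_res + 1)))
                    for _, nuc in dims
                ),
            )
            for k in range(n_exp)
        ]
        centers = {"H": 8.0, "N": 118.0, "C": 50.0}
        n_meas = int(rng.integers(1, max_measured + 1))
        measured[spec.name] = [
            MeasuredPeak(
                peak_id=k + 1,
                spectrum=spec.name,
                position=tuple(
                    centers[nuc] + float(rng.normal(0, 2.0)) for _, nuc in dims
                ),
            )
            for k in range(n_meas)
        ]
    return build_instance(
        sequence, spectra, expected, measured, stats, ToleranceConfig()
    )
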