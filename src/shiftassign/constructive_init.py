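"""Constructive, search-space-reducing creation of initial populations.

Each atom starts with a statistical search window [μ − k·σ − t, μ + k·σ + t]
(t = the nucleus tolerance; atoms without statistics start unbounded).  An
individual is built by visiting the expected peaks in a random order; each
peak scans its spectrum's measured peaks in file order and takes the FIRST
one whose every coordinate lies inside the current window of the matching
atom.  On success, the coordinates are appended to the atoms' frequency lists
and each touched atom's window collapses to [mean(freq) − t, mean(freq) + t],
so later peaks must stay consistent with earlier choices.  Peaks with no
fitting measured peak stay unassigned.  The search-space reduction applies
only during initialization; the evolutionary operators are unrestricted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .peak_io import ValidationError
from .problem_model import NONE, Chromosome, ProblemInstance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InitConfig:
    """Initial-population parameters.

    ``random_fraction`` individuals are drawn uniformly instead of
    constructively; ``k_sigma`` is the half-width multiplier of the initial
    statistical range before tolerance widening.
    """

    population_size: int = 50
    random_fraction: float = 0.0
    k_sigma: float = 2.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValidationError("population_size must be >= 1")
        if not 0.0 <= self.random_fraction <= 1.0:
            raise ValidationError("random_fraction must lie in [0, 1]")


class SearchWindows:
    """Per-atom ppm search windows with accumulated frequency lists."""

    def __init__(self, lower: np.ndarray, upper: np.ndarray, tol: np.ndarray):
        self.lower = lower
        self.upper = upper
        self.tol = tol
        self.freq_sum = np.zeros(len(lower))
        self.freq_count = np.zeros(len(lower), dtype=np.int64)

    def copy(self) -> "SearchWindows":
        return SearchWindows(self.lower.copy(), self.upper.copy(), self.tol)

    def add(self, atom: int, value: float) -> None:
        """Record a contribution and recentre the window on the running mean."""
        self.freq_sum[atom] += value
        self.freq_count[atom] += 1
        mean = self.freq_sum[atom] / self.freq_count[atom]
        self.lower[atom] = mean - self.tol[atom]
        self.upper[atom] = mean + self.tol[atom]


def init_windows(instance: ProblemInstance, k_sigma: float = 2.0) -> SearchWindows:
    """Statistical windows [μ − k·σ − t, μ + k·σ + t]; unbounded without statistics."""
    mu, sigma, tol = instance.atom_mu, instance.atom_sigma, instance.atom_tol
    lower = mu - k_sigma * sigma - tol
    upper = mu + k_sigma * sigma + tol
    missing = np.isnan(mu)
    if missing.any():
        logger.info("%d atoms without statistics start with unbounded windows",
                    int(missing.sum()))
        lower[missing] = -math.inf
        upper[missing] = math.inf
    return SearchWindows(lower, upper, tol)


def construct_individual(
    instance: ProblemInstance, windows: SearchWindows, rng: np.random.Generator
) -> Chromosome:
    """Build one constructive individual (mutates ``windows``; pass a fresh copy)."""
    chromosome = instance.empty_chromosome()
    order = rng.permutation(instance.L)
    for g in order:
        si = instance.gene_spectrum[g]
        positions = instance.measured_positions[si]
        if positions.shape[0] == 0:
            continue
        atoms = instance.gene_atoms[g]
        lo = windows.lower[atoms]
        hi = windows.upper[atoms]
        fits = np.flatnonzero(
            np.all((positions >= lo) & (positions <= hi), axis=1)
        )
        if fits.size == 0:
            continue
        m = int(fits[0])
        chromosome[g] = m
        for d, atom in enumerate(atoms):
            windows.add(int(atom), float(positions[m, d]))
    return chromosome


def build_population(
    instance: ProblemInstance,
    config: InitConfig = InitConfig(),
    rng: Optional[np.random.Generator] = None,
) -> list[Chromosome]:
    """Constructive individuals plus an optional uniformly random remainder."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_constructive = math.ceil((1.0 - config.random_fraction) * config.population_size)
    base = init_windows(instance, config.k_sigma)
    population = [
        construct_individual(instance, base.copy(), rng) for _ in range(n_constructive)
    ]
    population.extend(
        instance.random_chromosome(rng)
        for _ in range(config.population_size - n_constructive)
    )
    return population
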