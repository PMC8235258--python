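# Methods

## Problem model

A problem instance consists of a protein sequence, a set of 2–4-dimensional
spectra, per-spectrum lists of expected peaks (ordered atom tuples) and
measured peaks (ppm coordinates), a shift-statistics table with a mean μ and
standard deviation σ per (residue type, atom name), and per-nucleus
tolerances t (defaults 0.03 ppm for ¹H, 0.4 ppm for ¹³C and ¹⁵N — the
typical experimental accuracy of picked peak positions).

A candidate assignment is an integer chromosome: one gene per expected peak,
in the fixed order obtained by concatenating the per-spectrum expected lists
in spectrum order. A gene holds the 0-based index of a measured peak of the
same spectrum, or −1 for "unassigned". Two structural constraints — an
expected peak maps to at most one measured peak, and only within its own
spectrum — hold by construction; the third physical constraint (the spread
of one atom's induced shifts must be comparable to the tolerance) is not a
hard constraint but is absorbed into the alignment objective.

Atoms are shared across spectra through a global registry keyed by
(atom name, residue number); a chromosome therefore induces, per atom, a
list of ppm contributions whose mean δ̄(a) is the atom's assigned shift.

## Objectives and the aggregated score

The four minimization objectives and the aggregated score G are given in the
README. Design points worth recording:

* **Kernel form.** Q₁ and Q₂ are Gaussian kernels — smooth, bounded in
  (0, 1], maximal at exact agreement, and parameterized directly by the
  library σ and the experimental tolerance. Other monotone kernels
  (truncated Gaussians, probability ratios) would serve; the kernel is a
  single function (`scoring.gaussian_kernel`) and easy to swap.
* **δ̄(a)** is the unweighted arithmetic mean of all contributions, both in
  scoring and in the initializer's window updates.
* **Atoms without a statistics entry** contribute Q₁ = 0 but still count in
  |A| and in G's denominator: completeness must not be inflated by
  unscorable atoms. They are logged once per instance.
* **F₂ is an unweighted sum** of Q₂ over contributions; only G divides the
  alignment term by the degeneracy b(n).
* G's denominator counts every atom once with weight w₁ = 4 and every
  (atom, expected peak) incidence once with weight w₂ = 1, so G is
  normalized per instance and comparable across runs.

The evaluator flattens every (gene, dimension) pair into a slot and scores a
chromosome with numpy gathers and bincounts (~50 µs for ~190 genes); an
independently written dictionary-and-loops implementation of the same
definitions lives in the test suite and the two are required to agree to
1e-9 on fuzzed and exhaustively enumerated instances.

## Constructive initialization

Each atom starts with the search window [μ − kσ − t, μ + kσ + t]; k = 2 by
default (the statistical range is named but its width is a free choice;
±2σ covers ~95% of library values). Atoms without statistics start
unbounded. One individual is built by visiting expected peaks in a uniformly
random order; each peak scans its spectrum's measured list in file order and
takes the first peak lying inside all of its atoms' windows, after which
each touched atom's window collapses to [mean(contributions) − t, mean + t].
Unassigned genes stay −1. The visiting order is the only randomized element;
a measured peak may be chosen repeatedly (degeneracy is penalized by F₄, not
forbidden). Window updates recentre on the running mean but do not re-widen
by σ. The reduction applies only during initialization.

A configurable fraction of the population (default 0) is instead drawn
uniformly from {−1} ∪ measured indices per gene.

## Optimizers

All three algorithms use populations of N′ = 50 (even, for pairwise
recombination), uniform per-gene-exchange crossover applied with probability
`crossover_rate` (default 1.0), and single-gene uniform-reset mutation
(default rate 1.0 = one gene redrawn per individual; the "dynamic" rate
1/L resets each gene independently with probability 1/L).

* **GA** scalarizes the four objectives as the equal-weight mean of their
  min–max normalizations within the current population (ties broken by
  higher G), selects by binary tournament, and is elitist in G.
* **NSGA-II** uses fast non-dominated sorting, crowding distance (boundary
  members +∞, zero-range objectives contribute 0), crowded-comparison
  binary tournaments, and (μ+λ) survival truncating the last front by
  descending crowding.
* **NSGA-III** generates children without selection pressure (random
  pairing), then survives by non-dominated sorting plus reference-direction
  niching: Das–Dennis directions with 6 divisions per axis (84 points ≥ N′
  on the 4-objective simplex), ideal-point translation, extreme points via
  an achievement scalarizing function, intercept normalization with a
  range-normalization fallback for degenerate hyperplanes, association by
  perpendicular distance, and niche-count-ascending selection with random
  tie-breaks (closest member for empty niches).

A hill-climbing pass scans genes in index order and adopts, per gene, the
best strict G-improvement over all same-spectrum values including −1
(best-improvement policy). Optionally every evolutionary iteration is
followed by one such pass applied to the current best-G member (the
hyper-heuristic combination); G of the best member is then monotone.

Multi-objective runs report the first-front member with maximal G, so the
downstream consolidation always receives exactly one assignment per run.

## Repetition and consolidation

The pipeline runs the optimizer R times (default 10) with per-repetition
seeds spawned deterministically from the master seed, projects each reported
chromosome to a shift list (value = δ̄(a), sd = contribution spread), and
consolidates per atom by single-linkage clustering of the R values at the
atom's tolerance. The consensus is the mean of the largest cluster; ties go
to the cluster with smaller spread, then lower mean. Atoms absent from every
run are absent from the consensus.

Evaluation against a reference list classifies each reference atom:
assigned and |Δ| < t → correct; assigned and |Δ| ≥ t → wrong (strictly, so a
deviation exactly at the tolerance is wrong); otherwise unassigned. Atoms
not in the reference are ignored. Mutual agreement between algorithms is the
Venn partition of their correct-atom sets, with percentages relative to the
union.

## Synthetic data generator

The generator emulates the structure of triple-resonance datasets: true
shifts are drawn independently per atom from Normal(μ, σ) of the statistics
table; expected peaks are enumerated from five built-in simplified spectrum
templates (¹⁵N-HSQC; HNCA with intra- and inter-residue CA; HNCO; CBCANH
with CA/CB of residues i and i−1; ¹³C-HSQC with HA–CA and HB–CB pairs).
Templates are data (atom name + residue offset per dimension) and can be
extended. Amide-rooted patterns skip prolines and the first residue;
glycines carry no CB/HB. Random sequences exclude proline so every
non-terminal residue anchors the amide-rooted templates.

Degradation follows the difficult-spectra regime: each expected peak is
observed with probability 1 − p_missing (default 0.5), observed positions
carry per-nucleus Gaussian noise (default tolerance/3), and
⌊artifact_ratio × observed⌋ artifact peaks (default ratio 1.0) are placed
uniformly over each spectrum's occupied bounding box. Peak ids are shuffled
so file order is uninformative. The true mapping and shifts are retained,
so the ground-truth chromosome and a reference shift list are available for
end-to-end grading.

What the generator does **not** model: peak overlap and merging, lineshapes
and intensities, ¹³C folding/aliasing, correlated (spin-system-wise) missing
peaks, pseudo-atom degeneracy, and artifact clustering near real peaks.
Passing recovery tests therefore demonstrate the machinery on idealized
spectra, not performance on experimental data.

## Problem sizes and observed behaviour

The recovery benchmark uses 20-residue sequences over the five templates
(~190 expected peaks, ~135 atoms) with GA populations of 50, 2000
iterations and 5 repetitions — sizes chosen so a full benchmark completes in
minutes on one core while still being far beyond exhaustive search
(log₁₀ |space| ≈ 309).

A property of this formulation worth knowing: because true shifts are drawn
from the same Normal(μ, σ) the initializer's windows are built from, a
μ ± 2σ window covers essentially every same-type peak, so the first-fit
constructive choices are near-arbitrary and the initial population consists
of internally consistent but largely misplaced spin systems. Single-gene
moves out of such a local optimum are penalized by the alignment objective
before the compensating moves are made, so the G landscape has deep
consistent-but-wrong basins. Best-improvement hill climbing converges to
G ≈ 0.71 against G ≈ 0.85 for the ground truth on the clean benchmark, and
the GA with the operators above recovers roughly a third to a half of the
atoms after consolidation rather than approaching 100%. Coordinated
multi-gene moves (spin-system swaps) would be required to do materially
better; they are deliberately out of scope of the present operator set.

## Numerical and degenerate-input choices

* Empty instances (no atoms in any expected peak) raise on scoring rather
  than returning 0/0.
* Spectra with no measured peaks contribute nothing to the search-space
  count; genes of such spectra can only be −1.
* The search-space count follows the convention M^E per spectrum (the
  unassigned option is not counted), although the representation itself
  allows (M+1)^E.
* Crowding distances use stable sorts, so equal objective values tie-break
  by index deterministically.
* NSGA-III normalization falls back to per-objective range normalization
  when the extreme-point system is singular or yields non-positive
  intercepts.
* All randomness flows through `numpy.random.Generator`; every public entry
  point takes a seed, spawned seeds are reduced below 2³¹, and fixed seeds
  give bit-identical results.
* Shift lists are printed at 3 decimals; round-trips are exact at that
  precision.

## Limitations

Pseudo-atoms and stereo-specific assignments are not modelled (each listed
atom name is atomic). Peak aliasing, multi-chain proteins and BMRB/STAR
I/O are out of scope. The expected-peak file dialect is a minimal
package-defined text format rather than any vendor format; measured peaks
use the XEASY dialect.
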