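"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the scoring and selection
definitions with plain Python dictionaries and O(N²) loops, deliberately
sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import math


def brute_contributions(instance, chromosome):
    """atom -> list of ppm contributions, by scanning every gene and dimension."""
    out = {}
    for g, (si, peak) in enumerate(instance.genes):
        m = int(chromosome[g])
        if m < 0:
            continue
        position = instance.measured[instance.spectra[si].name][m].position
        for d, atom in enumerate(peak.atoms):
            out.setdefault(atom, []).append(position[d])
    return out


def brute_degeneracy(instance, chromosome, gene):
    """b(n) by pairwise comparison over all genes."""
    si, _ = instance.genes[gene]
    target = int(chromosome[gene])
    assert target >= 0
    count = 0
    for g, (sj, _) in enumerate(instance.genes):
        if sj == si and int(chromosome[g]) == target:
            count += 1
    return count


def brute_objectives(instance, chromosome):
    """(F1, F2, F3, F4) from the definitions."""
    contribs = brute_contributions(instance, chromosome)
    means = {a: sum(v) / len(v) for a, v in contribs.items()}
    f1 = 0.0
    for atom, mean in means.items():
        rtype = instance.sequence.residue_type(atom.residue_number)
        if (rtype, atom.name) in instance.statistics:
            mu, sigma = instance.statistics.get(rtype, atom.name)
            f1 -= math.exp(-((mean - mu) ** 2) / (2 * sigma**2))
    f2 = 0.0
    for atom, values in contribs.items():
        tol = instance.tolerances.for_atom(atom)
        for v in values:
            f2 -= math.exp(-((v - means[atom]) ** 2) / (2 * tol**2))
    f3 = -float(len(contribs))
    f4 = 0.0
    for g, (si, peak) in enumerate(instance.genes):
        if int(chromosome[g]) >= 0:
            f4 += len(peak.atoms) * brute_degeneracy(instance, chromosome, g)
    return (f1, f2, f3, f4)


def brute_global_score(instance, chromosome, w1=4.0, w2=1.0):
    """G from the aggregated-score definition."""
    contribs = brute_contributions(instance, chromosome)
    means = {a: sum(v) / len(v) for a, v in contribs.items()}
    numerator = 0.0
    for atom, mean in means.items():
        rtype = instance.sequence.residue_type(atom.residue_number)
        if (rtype, atom.name) in instance.statistics:
            mu, sigma = instance.statistics.get(rtype, atom.name)
            numerator += w1 * math.exp(-((mean - mu) ** 2) / (2 * sigma**2))
    for g, (si, peak) in enumerate(instance.genes):
        m = int(chromosome[g])
        if m < 0:
            continue
        b = brute_degeneracy(instance, chromosome, g)
        position = instance.measured[instance.spectra[si].name][m].position
        for d, atom in enumerate(peak.atoms):
            tol = instance.tolerances.for_atom(atom)
            q2 = math.exp(-((position[d] - means[atom]) ** 2) / (2 * tol**2))
            numerator += w2 * q2 / b
    n_slots = sum(len(peak.atoms) for _, peak in instance.genes)
    denominator = w1 * instance.n_atoms + w2 * n_slots
    return numerator / denominator


def brute_dominates(u, v):
    return all(a <= b for a, b in zip(u, v)) and any(a < b for a, b in zip(u, v))


def brute_fronts(objectives):
    """Pareto fronts by repeated scanning."""
    remaining = list(range(len(objectives)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(
                brute_dominates(objectives[j], objectives[i])
                for j in remaining
                if j != i
            )
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


def brute_crowding(front_objectives):
    """Crowding distances computed objective by objective with explicit loops."""
    n = len(front_objectives)
    m = len(front_objectives[0])
    if n <= 2:
        return [math.inf] * n
    dist = [0.0] * n
    for j in range(m):
        order = sorted(range(n), key=lambda i: (front_objectives[i][j], i))
        lo = front_objectives[order[0]][j]
        hi = front_objectives[order[-1]][j]
        dist[order[0]] = math.inf
        dist[order[-1]] = math.inf
        if hi > lo:
            for k in range(1, n - 1):
                i = order[k]
                if dist[i] != math.inf:
                    gap = (
                        front_objectives[order[k + 1]][j]
                        - front_objectives[order[k - 1]][j]
                    )
                    dist[i] += gap / (hi - lo)
    return dist


def brute_crowded_truncation(objectives, n_keep):
    """NSGA-II survival: whole fronts, last front by descending crowding."""
    fronts = brute_fronts(objectives)
    chosen = []
    for front in fronts:
        if len(chosen) + len(front) <= n_keep:
            chosen.extend(front)
        else:
            dist = brute_crowding([objectives[i] for i in front])
            ranked = sorted(
                range(len(front)), key=lambda k: (-dist[k], front[k])
            )
            chosen.extend(front[k] for k in ranked[: n_keep - len(chosen)])
            break
        if len(chosen) == n_keep:
            break
    return chosen
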