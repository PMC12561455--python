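"""Independent brute-force oracles used to cross-check the package.

These are written directly from the metric definitions and deliberately
share no code with the implementation: plain dict/loop arithmetic over
(peptide, sample) cells.
"""
from __future__ import annotations

import math


def brute_specificity(cells, species_of, peptide):
    """cells: dict (peptide, sample) -> abundance or None for missing."""
    seen = {
        species_of[s]
        for (p, s), v in cells.items()
        if p == peptide and v is not None
    }
    if not seen:
        raise ValueError("never observed")
    return 1.0 / len(seen)


def brute_sensitivity(cells, species_of, individual_of, peptide, species):
    individuals = {individual_of[s] for s in species_of if species_of[s] == species}
    found = {
        individual_of[s]
        for (p, s), v in cells.items()
        if p == peptide and v is not None and species_of[s] == species
    }
    return len(found) / len(individuals)


def brute_exclusivity(cells, species_of, peptide, species):
    total = sum(
        v for (p, s), v in cells.items() if p == peptide and v is not None
    )
    if total <= 0:
        return 0.0
    in_species = sum(
        v
        for (p, s), v in cells.items()
        if p == peptide and v is not None and species_of[s] == species
    )
    return in_species**2 / total


def brute_combine_scores(probabilities, correlations):
    products = {
        sp: probabilities[sp] * max(correlations[sp], 0.0) for sp in probabilities
    }
    total = sum(products.values())
    return {sp: v / total for sp, v in products.items()}


def brute_welch_p(a, b):
    """Two-sided Welch t-test from the textbook formulas (scipy only for the CDF)."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * t_dist.sf(abs(t), df)


def brute_collision_pairs(entries, tolerance_ppm, denominator="mean"):
    """All-pairs O(n^2) enumeration; entries: (key, species, mass)."""
    pairs = set()
    n = len(entries)
    for i in range(n):
        for j in range(i + 1, n):
            ka, sa, mass_a = entries[i]
            kb, sb, mass_b = entries[j]
            if sa == sb:
                continue
            ref = (mass_a + mass_b) / 2 if denominator == "mean" else min(mass_a, mass_b)
            if abs(mass_a - mass_b) / ref * 1e6 < tolerance_ppm:
                pairs.add(tuple(sorted([(ka, sa), (kb, sb)])))
    return pairs


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
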