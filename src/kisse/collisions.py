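"""Mass-collision analysis among species-specific peptides.

Counts cross-species peptide pairs whose monoisotopic masses fall within a
ppm tolerance; peptides involved in any such pair are ambiguous for
mass-only (fingerprinting) identification and are excluded from the
surviving marker counts.  Implemented as a sorted sliding window, which is
O(n log n + k) instead of the all-pairs O(n^2).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DataError, ValidationError

DEFAULT_MIN_MARKERS = 9


@dataclass(frozen=True)
class CollisionPair:
    peptide_a: str
    species_a: str
    peptide_b: str
    species_b: str
    delta_ppm: float


@dataclass
class CollisionReport:
    tolerance_ppm: float
    denominator: str
    pairs: list[CollisionPair]
    excluded_peptides: set[str]
    surviving_counts: dict[str, int]


def delta_ppm(mass_a: float, mass_b: float, denominator: str = "mean") -> float:
    """Relative mass difference in parts per million.

    ``denominator`` is ``"mean"`` (symmetric) or ``"min"``; the choice only
    matters for pairs sitting at the tolerance boundary.
    """
    if denominator == "mean":
        ref = (mass_a + mass_b) / 2.0
    elif denominator == "min":
        ref = min(mass_a, mass_b)
    else:
        raise ValidationError(f"unknown ppm denominator {denominator!r}")
    return abs(mass_a - mass_b) / ref * 1e6


def find_collisions(
    peptides: Iterable[Sequence],
    tolerance_ppm: float,
    denominator: str = "mean",
) -> CollisionReport:
    """All unordered cross-species pairs closer than ``tolerance_ppm``.

    ``peptides`` yields (peptide_key, species, mono_mass) triples; each
    peptide carries a single species annotation (it is species-specific).
    """
    if tolerance_ppm <= 0:
        raise ValidationError("tolerance_ppm must be positive")
    entries = [(str(k), str(s), float(m)) for k, s, m in peptides]
    for key, _, mass in entries:
        if not mass > 0:
            raise DataError(f"nonpositive mass for peptide {key!r}")
    entries.sort(key=lambda e: (e[2], e[0]))
    pairs: list[CollisionPair] = []
    n = len(entries)
    for i in range(n):
        key_i, sp_i, mass_i = entries[i]
        j = i + 1
        # window bound: any admissible pair satisfies diff < tol*1e-6*max(mass)
        while j < n and entries[j][2] - mass_i < tolerance_ppm * 1e-6 * entries[j][2]:
            key_j, sp_j, mass_j = entries[j]
            if sp_i != sp_j:
                d = delta_ppm(mass_i, mass_j, denominator)
                if d < tolerance_ppm:
                    a, b = sorted(((key_i, sp_i), (key_j, sp_j)))
                    pairs.append(CollisionPair(a[0], a[1], b[0], b[1], d))
            j += 1
    pairs.sort(key=lambda p: (p.peptide_a, p.peptide_b))
    excluded = {p.peptide_a for p in pairs} | {p.peptide_b for p in pairs}
    surviving: dict[str, int] = {}
    for key, sp, _ in entries:
        surviving.setdefault(sp, 0)
        if key not in excluded:
            surviving[sp] += 1
    return CollisionReport(
        tolerance_ppm=tolerance_ppm,
        denominator=denominator,
        pairs=pairs,
        excluded_peptides=excluded,
        surviving_counts=surviving,
    )


def pmf_reliability(
    surviving_counts: dict[str, int], min_markers: int = DEFAULT_MIN_MARKERS
) -> dict[str, bool]:
    """True where a species keeps at least ``min_markers`` unambiguous markers."""
    return {sp: count >= min_markers for sp, count in surviving_counts.items()}
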