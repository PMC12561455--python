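"""Per-peptide discrimination metrics and feature selection.

Three quantities are computed for every peptide on the linear normalized
abundance matrix:

* **specificity** — 1/N, with N the number of species the peptide was
  observed in (N counts species with at least one non-missing cell);
* **sensitivity** (per species) — fraction of that species' individuals in
  which the peptide was observed (replicates of one individual collapse by
  presence-OR);
* **exclusivity** (per species) — squared total abundance of the peptide
  over the species' samples divided by its total abundance over all
  samples, with missing cells contributing 0 to the sums.

From these the *informative* peptide set (species-specific peptides plus
widely quantified, between-species-variable peptides) and the per-species
top-N *feature panel* for the classifier are derived.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientDataError, ValidationError
from .matrix import SCALE_NORMALIZED, AbundanceMatrix


@dataclass
class PeptideMetrics:
    """Metric tables for every peptide of a matrix.

    Attributes
    ----------
    n_species_found : Series, peptide -> N (species with >=1 observation)
    specificity : Series, peptide -> 1/N (NaN for never-observed peptides)
    sensitivity : DataFrame, peptides x species
    exclusivity : DataFrame, peptides x species
    """

    n_species_found: pd.Series
    specificity: pd.Series
    sensitivity: pd.DataFrame
    exclusivity: pd.DataFrame

    def species_specific(self) -> pd.Series:
        """peptide -> species for peptides with specificity == sensitivity == 1."""
        solo = self.specificity == 1.0
        out = {}
        for pep in self.specificity.index[solo]:
            row = self.sensitivity.loc[pep]
            present = row.index[row > 0]
            if len(present) == 1 and row[present[0]] == 1.0:
                out[pep] = present[0]
        return pd.Series(out, dtype=object)


def compute_metrics(matrix: AbundanceMatrix) -> PeptideMetrics:
    """Compute specificity, sensitivity and exclusivity for all peptides."""
    if matrix.scale != SCALE_NORMALIZED:
        raise DataError("metrics are defined on the linear normalized scale")
    presence = matrix.presence()  # peptides x samples
    species = matrix.species
    individuals = matrix.individuals

    by_species = presence.T.groupby(species).any().T  # peptides x species
    n_species = by_species.sum(axis=1)
    with np.errstate(divide="ignore"):
        specificity = (1.0 / n_species).replace(np.inf, np.nan)

    # presence per individual (replicates collapse by OR), then species mean
    ind_presence = presence.T.groupby([species, individuals]).any()
    sensitivity = ind_presence.groupby(level=0).mean().T
    sensitivity = sensitivity.reindex(columns=sorted(sensitivity.columns))

    observed = matrix.observed_values()
    species_sums = observed.T.groupby(species).sum().T
    species_sums = species_sums.reindex(columns=sensitivity.columns)
    totals = observed.sum(axis=1)
    zero_total = totals <= 0
    if zero_total.any():
        warnings.warn(
            f"{int(zero_total.sum())} peptide(s) unquantified everywhere; "
            "their exclusivity is 0"
        )
    safe_totals = totals.where(~zero_total, 1.0)
    exclusivity = (species_sums**2).div(safe_totals, axis=0)
    exclusivity[zero_total] = 0.0

    return PeptideMetrics(
        n_species_found=n_species,
        specificity=specificity,
        sensitivity=sensitivity,
        exclusivity=exclusivity,
    )


def compute_specificity(peptide: str, matrix: AbundanceMatrix) -> float:
    """1/N for one peptide; errors if the peptide was never observed."""
    if peptide not in matrix.values.index:
        raise DataError(f"unknown peptide {peptide!r}")
    present = matrix.presence().loc[peptide]
    n = matrix.species[present.index[present]].nunique()
    if n == 0:
        raise DataError(f"peptide {peptide!r} was never observed")
    return 1.0 / n


def compute_sensitivity(peptide: str, species: str, matrix: AbundanceMatrix) -> float:
    if species not in set(matrix.species):
        raise DataError(f"unknown species {species!r}")
    if peptide not in matrix.values.index:
        raise DataError(f"unknown peptide {peptide!r}")
    samples = matrix.species.index[matrix.species == species]
    present = matrix.presence().loc[peptide, samples]
    inds = matrix.individuals[samples]
    seen = inds[present.to_numpy(dtype=bool)].nunique()
    return seen / inds.nunique()


def compute_exclusivity(peptide: str, species: str, matrix: AbundanceMatrix) -> float:
    if matrix.scale != SCALE_NORMALIZED:
        raise DataError("exclusivity is defined on the linear normalized scale")
    if species not in set(matrix.species):
        raise DataError(f"unknown species {species!r}")
    row = matrix.observed_values().loc[peptide]
    total = row.sum()
    if total <= 0:
        warnings.warn(f"peptide {peptide!r} unquantified everywhere; exclusivity 0")
        return 0.0
    in_species = row[matrix.species.index[matrix.species == species]].sum()
    return in_species**2 / total


# ----------------------------------------------------------------------
def _between_species_variation(
    matrix: AbundanceMatrix, statistic: str
) -> pd.Series:
    """Unitless spread of per-species mean abundances, per peptide."""
    observed = matrix.observed_values()
    species_means = observed.T.groupby(matrix.species).mean().T
    mean = species_means.mean(axis=1)
    if statistic == "cv":
        spread = species_means.std(axis=1, ddof=1)
    elif statistic == "relrange":
        spread = species_means.max(axis=1) - species_means.min(axis=1)
    else:
        raise ValidationError(f"unknown variation statistic {statistic!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = spread / mean
    return out.fillna(0.0)


def select_informative(
    matrix: AbundanceMatrix,
    metrics: PeptideMetrics | None = None,
    presence_frac: float = 0.25,
    variation_min: float = 0.03,
    variation_statistic: str = "cv",
) -> list[str]:
    """Union of species-specific peptides and widely quantified variable ones.

    Returns a lexicographically sorted peptide list: (a) peptides with
    specificity == 1 and sensitivity == 1 for their species; (b) peptides
    observed in at least ``presence_frac`` of all individuals whose
    between-species variation is at least ``variation_min``.
    """
    if metrics is None:
        metrics = compute_metrics(matrix)
    specific = set(metrics.species_specific().index)

    presence = matrix.presence()
    ind_presence = presence.T.groupby(matrix.individuals).any()
    frac_individuals = ind_presence.mean(axis=0)
    variation = _between_species_variation(matrix, variation_statistic)
    wide = set(
        frac_individuals.index[
            (frac_individuals >= presence_frac) & (variation >= variation_min)
        ]
    )
    return sorted(specific | wide)


# ----------------------------------------------------------------------
@dataclass
class FeaturePanel:
    """Per-species ranked species-specific peptides plus their union.

    ``feature_order`` concatenates the per-species lists in sorted species
    order and is the classifier's feature vector ordering.
    """

    per_species: dict[str, list[str]]
    n_top: int

    @property
    def feature_order(self) -> list[str]:
        out: list[str] = []
        for sp in sorted(self.per_species):
            out.extend(self.per_species[sp])
        return out

    @property
    def species(self) -> list[str]:
        return sorted(self.per_species)


def build_feature_panel(
    matrix: AbundanceMatrix,
    metrics: PeptideMetrics | None = None,
    n_top: int = 11,
) -> FeaturePanel:
    """Top ``n_top`` species-specific peptides per species by exclusivity.

    Ties break by lexicographic peptide key so repeated builds are
    identical.  A species with fewer than ``n_top`` species-specific
    peptides is an error (lower ``n_top`` globally instead).
    """
    if metrics is None:
        metrics = compute_metrics(matrix)
    specific = metrics.species_specific()
    panel: dict[str, list[str]] = {}
    for sp in matrix.species_list:
        candidates = list(specific.index[specific == sp])
        if len(candidates) < n_top:
            raise InsufficientDataError(
                f"species {sp!r} has only {len(candidates)} species-specific "
                f"peptides, fewer than n_top={n_top}"
            )
        ranked = sorted(
            candidates, key=lambda p: (-metrics.exclusivity.loc[p, sp], p)
        )
        panel[sp] = ranked[:n_top]
    return FeaturePanel(per_species=panel, n_top=n_top)
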