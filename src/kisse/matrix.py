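"""Abundance matrices and their transformations.

The central container is :class:`AbundanceMatrix`: a peptides x samples grid
of abundances together with a missingness mask and per-sample species /
individual annotations.  Three scales exist and are tracked explicitly:

``raw``          XIC areas as exported by the search engine
``normalized``   each sample divided by its total non-missing abundance
``log10``        elementwise log10 of the (imputed) normalized values

Missing cells are NaN until imputed; the mask keeps recording which cells
were absent before imputation so that downstream presence/absence logic
(specificity, sensitivity, informative-peptide selection) is unaffected by
the imputed fill-in values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

SCALE_RAW = "raw"
SCALE_NORMALIZED = "normalized"
SCALE_LOG10 = "log10"


@dataclass
class AbundanceMatrix:
    """Peptides x samples abundance grid with annotations.

    Parameters
    ----------
    values
        Float DataFrame indexed by peptide_key with sample_id columns.
        NaN marks a missing (never observed) cell until imputation.
    missing_mask
        Boolean DataFrame aligned to ``values``; True exactly where no
        observation existed before imputation.
    species
        Series mapping sample_id -> species label.
    individuals
        Series mapping sample_id -> individual id.
    scale
        One of ``raw``, ``normalized``, ``log10``.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    species: pd.Series
    individuals: pd.Series
    scale: str = SCALE_RAW
    imputed: bool = field(default=False)

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.missing_mask.index) or list(
            self.values.columns
        ) != list(self.missing_mask.columns):
            raise ValidationError("values and missing_mask must share index/columns")
        missing_samples = [s for s in self.values.columns if s not in self.species.index]
        if missing_samples:
            raise ValidationError(
                f"samples without species annotation: {missing_samples[:5]}"
            )
        if self.scale not in (SCALE_RAW, SCALE_NORMALIZED, SCALE_LOG10):
            raise ValidationError(f"unknown scale {self.scale!r}")

    # ------------------------------------------------------------------
    @classmethod
    def from_tables(
        cls,
        tables: Mapping[str, pd.Series],
        manifest: pd.DataFrame,
        scale: str = SCALE_RAW,
    ) -> "AbundanceMatrix":
        """Assemble a matrix from per-sample abundance Series.

        ``manifest`` needs columns ``sample_id``, ``species``, ``individual``;
        its row order fixes the column order.  Peptides are sorted
        lexicographically for deterministic builds.
        """
        unknown = set(tables) - set(manifest["sample_id"])
        if unknown:
            raise ValidationError(f"samples absent from manifest: {sorted(unknown)[:5]}")
        order = [s for s in manifest["sample_id"] if s in tables]
        frame = pd.DataFrame({s: tables[s] for s in order}, dtype=float)
        frame = frame.sort_index()
        mask = frame.isna()
        man = manifest.set_index("sample_id")
        return cls(
            values=frame,
            missing_mask=mask,
            species=man.loc[order, "species"],
            individuals=man.loc[order, "individual"],
            scale=scale,
        )

    # ------------------------------------------------------------------
    @property
    def n_peptides(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def species_list(self) -> list[str]:
        return sorted(self.species.unique())

    def presence(self) -> pd.DataFrame:
        """Boolean grid: True where an actual observation existed."""
        return ~self.missing_mask

    def observed_values(self) -> pd.DataFrame:
        """Values with imputed/missing cells replaced by 0 (for sum-based metrics)."""
        return self.values.where(~self.missing_mask, 0.0).fillna(0.0)

    def copy(self) -> "AbundanceMatrix":
        return replace(
            self,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            species=self.species.copy(),
            individuals=self.individuals.copy(),
        )


# ----------------------------------------------------------------------
def normalize_total(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide every sample by its total non-missing abundance.

    Missing cells stay missing.  Idempotent: a complete normalized sample
    sums to 1 and dividing by 1 changes nothing.
    """
    if matrix.scale == SCALE_LOG10:
        raise DataError("cannot total-normalize a log10-scale matrix")
    vals = matrix.values
    if (vals < 0).any().any():
        bad = vals.columns[(vals < 0).any()][0]
        raise DataError(f"negative abundance in sample {bad!r}")
    totals = vals.sum(axis=0, skipna=True)
    dead = totals.index[(totals <= 0) | vals.isna().all(axis=0)]
    if len(dead):
        raise DataError(
            f"sample(s) with no positive abundance: {list(dead[:5])}"
        )
    out = matrix.copy()
    out.values = vals.div(totals, axis=1)
    out.scale = SCALE_NORMALIZED
    return out


def impute_missing(
    matrix: AbundanceMatrix,
    rng_seed: int,
    divisor_low: float = 500000.0,
    divisor_high: float = 5000.0,
) -> AbundanceMatrix:
    """Replace missing cells by uniform draws from (m/divisor_low, m/divisor_high).

    ``m`` is the global minimum non-missing normalized abundance, so an
    imputed value can never outrank a real observation.  Cells are filled in
    a canonical (row-major over sorted peptide index) order from a single
    seeded generator, making the result reproducible from ``rng_seed``.
    """
    if matrix.scale != SCALE_NORMALIZED:
        raise DataError("imputation operates on the linear normalized scale")
    mask = matrix.values.isna().to_numpy()
    n_missing = int(mask.sum())
    if n_missing == 0:
        warnings.warn("matrix has no missing cells; imputation is a no-op")
        out = matrix.copy()
        out.imputed = True
        return out
    m = float(np.nanmin(matrix.values.to_numpy()))
    if not np.isfinite(m) or m <= 0:
        raise DataError("no positive non-missing abundance to anchor imputation")
    low, high = m / divisor_low, m / divisor_high
    rng = np.random.default_rng(rng_seed)
    draws = rng.uniform(low, high, size=n_missing)
    # uniform() can in principle return the lower bound; the interval is open
    on_edge = draws <= low
    while on_edge.any():
        draws[on_edge] = rng.uniform(low, high, size=int(on_edge.sum()))
        on_edge = draws <= low
    out = matrix.copy()
    filled = out.values.to_numpy(copy=True)
    filled[mask] = draws
    out.values = pd.DataFrame(filled, index=out.values.index, columns=out.values.columns)
    out.imputed = True
    return out


def impute_vector(
    vector: pd.Series,
    min_abundance: float,
    rng_seed: int,
    divisor_low: float = 500000.0,
    divisor_high: float = 5000.0,
) -> pd.Series:
    """Impute NaNs in a single normalized abundance vector.

    Used for query samples, where the anchoring minimum ``min_abundance``
    comes from the library rather than from the (single-sample) query.
    """
    if min_abundance <= 0 or not np.isfinite(min_abundance):
        raise DataError("min_abundance must be positive and finite")
    mask = vector.isna().to_numpy()
    if not mask.any():
        return vector.copy()
    low, high = min_abundance / divisor_low, min_abundance / divisor_high
    rng = np.random.default_rng(rng_seed)
    draws = rng.uniform(low, high, size=int(mask.sum()))
    on_edge = draws <= low
    while on_edge.any():
        draws[on_edge] = rng.uniform(low, high, size=int(on_edge.sum()))
        on_edge = draws <= low
    out = vector.copy().to_numpy(dtype=float)
    out[mask] = draws
    return pd.Series(out, index=vector.index)


def log_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log10; requires a complete, strictly positive matrix."""
    if matrix.scale == SCALE_LOG10:
        raise DataError("matrix is already on the log10 scale")
    vals = matrix.values.to_numpy()
    bad = ~(vals > 0) | ~np.isfinite(vals)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise DataError(
            "nonpositive or missing value at "
            f"(peptide={matrix.values.index[i]!r}, sample={matrix.values.columns[j]!r})"
        )
    out = matrix.copy()
    out.values = np.log10(matrix.values)
    out.scale = SCALE_LOG10
    return out
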