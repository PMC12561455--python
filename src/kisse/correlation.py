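"""Abundance-correlation scoring.

A query's informative-peptide abundance vector is correlated (Pearson by
default, on the log10 scale) against every library sample; coefficients are
then averaged per species.  A Welch two-sided t-test between the best
species' coefficients and the runner-up's quantifies how well separated the
top call is.

Missing cells (NaN) are handled pairwise-complete: each query/sample
coefficient uses only the peptides quantified in both.  Minimum-anchored
imputation is reserved for the classifier features — imputed fill-ins sit
orders of magnitude below real observations and would otherwise dominate
the correlation through sheer leverage, inflating similarity between any
two samples that merely share missingness.  Passing fully imputed inputs
(no NaNs) reproduces the all-cells behaviour.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InsufficientDataError


@dataclass
class CorrelationResult:
    per_sample: pd.Series
    averaged_by_species: pd.Series
    best_species: str
    p_value: float | None = None
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def _pearson_pair(x: np.ndarray, y: np.ndarray) -> float:
    if np.array_equal(x, y):  # identical vectors correlate exactly 1
        return 1.0 if np.ptp(x) > 0 else float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    # rounding can push |r| infinitesimally past 1; clamp to the valid range
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def _pairwise_columns(
    X: np.ndarray, q: np.ndarray, method: str, min_shared: int
) -> np.ndarray:
    """Correlation of q against each column of X over co-observed rows."""
    out = np.full(X.shape[1], np.nan)
    q_ok = ~np.isnan(q)
    for j in range(X.shape[1]):
        both = q_ok & ~np.isnan(X[:, j])
        if both.sum() < min_shared:
            continue
        x, y = q[both], X[both, j]
        if method == "spearman":
            x, y = stats.rankdata(x), stats.rankdata(y)
        out[j] = _pearson_pair(x, y)
    return out


def correlate_sample(
    query: pd.Series,
    library_matrix: pd.DataFrame,
    species: pd.Series,
    method: str = "pearson",
    exclude_sample: str | None = None,
    min_shared_peptides: int = 3,
) -> CorrelationResult:
    """Correlate one abundance vector against every library sample.

    ``query`` and ``library_matrix`` must already be on the same scale
    (log10 of normalized abundances in the standard pipeline).  NaN cells
    mark missing observations; each coefficient uses the pairwise-complete
    peptide set.  Fewer than ``min_shared_peptides`` peptides shared with
    the library as a whole is an error; a single sample with insufficient
    overlap (or zero variance) yields NaN and is dropped from the species
    averages with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise DataError(f"unknown correlation method {method!r}")
    cols = [c for c in library_matrix.columns if c != exclude_sample]
    if not cols:
        raise InsufficientDataError("no library samples to correlate against")
    shared = query.index.intersection(library_matrix.index)
    observed = query.loc[shared].notna().sum()
    if observed < min_shared_peptides:
        raise InsufficientDataError(
            f"only {observed} observed peptides shared with the library "
            f"(need >= {min_shared_peptides})"
        )
    q = query.loc[shared].to_numpy(dtype=float)
    if np.nanstd(q) == 0:
        raise DataError("query vector has zero variance; correlation undefined")
    X = library_matrix.loc[shared, cols].to_numpy(dtype=float)
    r = _pairwise_columns(X, q, method, min_shared_peptides)
    per_sample = pd.Series(r, index=cols)
    if per_sample.isna().any():
        warnings.warn(
            f"{int(per_sample.isna().sum())} library sample(s) had insufficient "
            "overlap or zero variance; excluded from species averages"
        )
    averaged = per_sample.groupby(species[cols]).mean().sort_index()
    best = averaged.idxmax()
    return CorrelationResult(
        per_sample=per_sample, averaged_by_species=averaged, best_species=str(best)
    )


def group_ttest(
    per_sample_correlations: pd.Series, species_labels: pd.Series
) -> float:
    """Welch two-sided p-value: best species' correlations vs the runner-up's.

    Groups are ranked by mean correlation (ties by name). Returns NaN with a
    warning when either group has fewer than two samples.
    """
    labels = species_labels[per_sample_correlations.index]
    means = per_sample_correlations.groupby(labels).mean()
    if len(means) < 2:
        warnings.warn("fewer than two species groups; t-test undefined")
        return float("nan")
    order = sorted(means.index, key=lambda s: (-means[s], s))
    best, runner = order[0], order[1]
    a = per_sample_correlations[labels == best]
    b = per_sample_correlations[labels == runner]
    if len(a) < 2 or len(b) < 2:
        warnings.warn("a comparison group has a single sample; p-value is NA")
        return float("nan")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def pairwise_ttests(
    per_sample_correlations: pd.Series, species_labels: pd.Series
) -> dict[tuple[str, str], float]:
    """Welch p-values for every species pair (verbose reporting)."""
    labels = species_labels[per_sample_correlations.index]
    groups = {s: per_sample_correlations[labels == s] for s in sorted(labels.unique())}
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            out[(a, b)] = float("nan")
        else:
            out[(a, b)] = float(
                stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
            )
    return out
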