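"""Final scoring: combine classifier probabilities with averaged
correlations, apply the in-database cutoff and emit a report.

The prediction score for species *i* is the normalized product

    score_i = p_i * c_i / sum_j p_j * c_j

of classifier probability ``p_i`` and averaged correlation ``c_i``
(negative correlations floored at 0 by default).  A sample whose maximum
averaged correlation falls below the cutoff (0.6 by default) is declared
not-in-database and the correlation argmax is reported as the closest
library species instead.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .correlation import correlate_sample, group_ttest, pairwise_ttests
from .errors import DataError, InsufficientDataError
from .forest import predict_proba
from .matrix import impute_vector

if TYPE_CHECKING:  # pragma: no cover
    from .library import SpeciesLibrary

IN_DB_CUTOFF = 0.6


@dataclass
class PredictionReport:
    sample_id: str
    per_species: pd.DataFrame  # columns: probability, averaged_correlation, prediction_score
    in_database: bool
    best_species: str
    closest_species: str | None
    p_value: float
    cutoff_used: float
    n_query_peptides: int
    n_usable_peptides: int

    def verdict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "in_database": bool(self.in_database),
            "best_species": self.best_species if self.in_database else None,
            "closest_species": self.closest_species,
            "p_value": None if np.isnan(self.p_value) else float(self.p_value),
            "cutoff": float(self.cutoff_used),
            "n_query_peptides": int(self.n_query_peptides),
            "n_usable_peptides": int(self.n_usable_peptides),
        }

    def write(self, out_dir: str | Path) -> None:
        """TSV score table plus JSON verdict."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_species.rename_axis("species").to_csv(
            out / f"{self.sample_id}.scores.tsv", sep="\t"
        )
        (out / f"{self.sample_id}.verdict.json").write_text(
            json.dumps(self.verdict(), indent=2) + "\n"
        )


def combine_scores(
    probabilities: Mapping[str, float],
    averaged_correlations: Mapping[str, float],
    floor_negative: bool = True,
) -> dict[str, float]:
    """Normalized probability-times-correlation score per species."""
    if set(probabilities) != set(averaged_correlations):
        raise DataError("probability and correlation maps cover different species")
    products = {}
    for sp in sorted(probabilities):
        c = averaged_correlations[sp]
        if floor_negative:
            c = max(c, 0.0)
        products[sp] = probabilities[sp] * c
    total = sum(products.values())
    if total <= 0:
        raise DataError("all probability x correlation products are zero; no evidence")
    return {sp: v / total for sp, v in products.items()}


def decide_in_database(
    averaged_correlations: Mapping[str, float], cutoff: float = IN_DB_CUTOFF
) -> tuple[bool, str]:
    """(in_database, best-or-closest species); correlation == cutoff counts as in."""
    if not averaged_correlations:
        raise DataError("empty correlation map")
    best = max(sorted(averaged_correlations), key=lambda s: averaged_correlations[s])
    return averaged_correlations[best] >= cutoff, best


def predict_sample(
    library: "SpeciesLibrary",
    query_table: pd.Series,
    sample_id: str = "query",
    seed: int = 0,
    exclude_sample: str | None = None,
    verbose_pairwise: bool = False,
) -> PredictionReport:
    """Run the full identification pipeline on one sample's raw abundances.

    ``query_table`` maps peptide_key -> raw abundance (NaN/0 = missing).
    The query is normalized by its own total, restricted to the library's
    informative peptides, imputed with the library's minimum normalized
    abundance, log10-transformed, then scored by classifier + correlation.
    ``exclude_sample`` enables self-exclusion when re-predicting a library
    member.
    """
    cfg = library.config
    q = query_table.dropna()
    q = q[q > 0]
    if q.empty:
        raise DataError(f"sample {sample_id!r} has no positive abundances")
    if not q.index.is_unique:
        raise DataError(f"sample {sample_id!r} has duplicated peptide keys")
    qn = q / q.sum()

    informative = library.informative
    observed = qn.index.intersection(informative)
    if len(observed) == 0:
        raise InsufficientDataError(
            f"sample {sample_id!r} shares no usable peptides with the library"
        )
    if len(observed) < cfg["correlation"]["min_shared_peptides"]:
        raise InsufficientDataError(
            f"sample {sample_id!r} has only {len(observed)} peptides in the "
            "library's informative set"
        )
    vec = pd.Series(np.nan, index=pd.Index(informative, name="peptide"), dtype=float)
    vec[observed] = qn[observed]
    imputed = impute_vector(
        vec,
        library.min_normalized_abundance,
        rng_seed=seed,
        divisor_low=cfg["imputation"]["divisor_low"],
        divisor_high=cfg["imputation"]["divisor_high"],
    )

    if cfg["correlation"].get("missing_policy", "pairwise_complete") == "imputed":
        corr_query = np.log10(imputed)
        corr_library = library.log.values.loc[informative]
    else:
        # pairwise-complete: keep NaN at unobserved cells on both sides
        corr_query = np.log10(vec)
        corr_library = (
            library.log.values.loc[informative]
            .where(~library.log.missing_mask.loc[informative])
        )
    corr = correlate_sample(
        corr_query,
        corr_library,
        library.log.species,
        method=cfg["correlation"]["method"],
        exclude_sample=exclude_sample,
        min_shared_peptides=cfg["correlation"]["min_shared_peptides"],
    )
    # classifier features always use minimum-anchored imputation
    feature_vec = np.log10(imputed).loc[library.classifier.feature_order]
    probs = predict_proba(library.classifier, feature_vec)
    corrs = dict(corr.averaged_by_species)
    scores = combine_scores(
        probs, corrs, floor_negative=cfg["prediction"]["floor_negative_correlations"]
    )
    cutoff = cfg["cutoffs"]["in_db"]
    in_db, closest = decide_in_database(corrs, cutoff)
    best = max(sorted(scores), key=lambda s: scores[s]) if in_db else closest
    p_value = group_ttest(corr.per_sample, library.log.species)
    if verbose_pairwise:
        corr.pairwise_p = pairwise_ttests(corr.per_sample, library.log.species)

    table = pd.DataFrame(
        {
            "probability": pd.Series(probs),
            "averaged_correlation": pd.Series(corrs),
            "prediction_score": pd.Series(scores),
        }
    ).sort_index()
    return PredictionReport(
        sample_id=sample_id,
        per_species=table,
        in_database=in_db,
        best_species=best,
        closest_species=None if in_db else closest,
        p_value=p_value,
        cutoff_used=cutoff,
        n_query_peptides=int(len(q)),
        n_usable_peptides=int(len(observed)),
    )
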