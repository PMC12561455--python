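"""Species library: build, validate submissions, expand.

A library bundles everything a prediction needs: the reference abundance
matrix (linear normalized view with missingness, plus an imputed log10
view), the manifest, the informative peptide set, the per-species feature
panel, the trained forest, the cutoffs and the build seed.  Builds are
deterministic under a fixed seed; ``content_hash`` fingerprints the result.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import matrix as mx
from .config import DEFAULTS, deep_merge
from .correlation import correlate_sample
from .errors import ValidationError
from .forest import ClassifierState, train
from .metrics import (
    FeaturePanel,
    PeptideMetrics,
    build_feature_panel,
    compute_metrics,
    select_informative,
)

MANIFEST_COLUMNS = ("sample_id", "species", "individual")
RECOMMENDED_METADATA = ("bone_element", "age", "sex", "origin")
MIN_INDIVIDUALS = 3


@dataclass
class SpeciesLibrary:
    linear: mx.AbundanceMatrix  # normalized linear scale, NaN at missing cells
    log: mx.AbundanceMatrix  # imputed, log10 scale
    manifest: pd.DataFrame
    informative: list[str]
    panel: FeaturePanel
    classifier: ClassifierState
    min_normalized_abundance: float
    seed: int
    config: dict[str, Any]
    metrics: PeptideMetrics | None = field(default=None, repr=False)

    @property
    def species(self) -> list[str]:
        return self.linear.species_list

    def content_hash(self) -> str:
        """SHA-256 over the model-defining content.

        The log view is derived deterministically from the linear view plus
        the seed, so hashing the linear matrix (at 9 significant digits, to
        absorb float renormalization noise), the peptide selections and the
        seed pins down the whole model.
        """
        h = hashlib.sha256()
        h.update(json.dumps(self.species).encode())
        h.update(json.dumps(list(self.linear.values.columns)).encode())
        h.update(json.dumps(self.informative).encode())
        h.update(json.dumps(self.panel.per_species, sort_keys=True).encode())
        h.update(self.linear.values.to_csv(float_format="%.9g").encode())
        h.update(str(self.seed).encode())
        return h.hexdigest()


def validate_manifest(manifest: pd.DataFrame, tables: Mapping[str, pd.Series]) -> None:
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise ValidationError(f"manifest lacks required column(s): {missing_cols}")
    if manifest["sample_id"].duplicated().any():
        dupes = manifest["sample_id"][manifest["sample_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate sample_id in manifest: {dupes[:5]}")
    unknown = set(tables) - set(manifest["sample_id"])
    if unknown:
        raise ValidationError(
            f"samples in tables but not in manifest: {sorted(unknown)[:5]}"
        )


def _check_min_individuals(manifest: pd.DataFrame, minimum: int = MIN_INDIVIDUALS) -> None:
    counts = manifest.groupby("species")["individual"].nunique()
    thin = counts.index[counts < minimum].tolist()
    if thin:
        detail = ", ".join(f"{sp} ({counts[sp]})" for sp in thin)
        raise ValidationError(
            f"species with fewer than {minimum} individuals: {detail}"
        )


def build_library(
    tables: Mapping[str, pd.Series],
    manifest: pd.DataFrame,
    config: Mapping[str, Any] | None = None,
    average_replicates: bool = False,
) -> SpeciesLibrary:
    """Build a complete library from raw per-sample abundance tables.

    ``tables`` maps sample_id -> Series of raw abundances (peptide_key
    index; NaN = missing).  With ``average_replicates`` the replicates of
    each individual are averaged into one pseudo-sample before building.
    """
    cfg = deep_merge(DEFAULTS, config or {})
    manifest = manifest.reset_index(drop=True)
    validate_manifest(manifest, tables)
    _check_min_individuals(manifest)

    if average_replicates:
        tables, manifest = _collapse_replicates(tables, manifest)

    raw = mx.AbundanceMatrix.from_tables(tables, manifest, scale=mx.SCALE_RAW)
    linear = mx.normalize_total(raw)
    metrics = compute_metrics(linear)
    informative = select_informative(
        linear,
        metrics,
        presence_frac=cfg["informative"]["presence_frac"],
        variation_min=cfg["informative"]["variation_min"],
        variation_statistic=cfg["informative"]["variation_statistic"],
    )
    panel = build_feature_panel(linear, metrics, n_top=cfg["panel"]["n_top"])

    m = float(np.nanmin(linear.values.to_numpy()))
    seed = int(cfg["imputation"]["seed"])
    if cfg["imputation"]["scope"] == "informative":
        sub = mx.AbundanceMatrix(
            values=linear.values.loc[informative],
            missing_mask=linear.missing_mask.loc[informative],
            species=linear.species,
            individuals=linear.individuals,
            scale=mx.SCALE_NORMALIZED,
        )
        imputed = mx.impute_missing(
            sub,
            rng_seed=seed,
            divisor_low=cfg["imputation"]["divisor_low"],
            divisor_high=cfg["imputation"]["divisor_high"],
        )
    else:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="matrix has no missing cells")
            imputed = mx.impute_missing(
                linear,
                rng_seed=seed,
                divisor_low=cfg["imputation"]["divisor_low"],
                divisor_high=cfg["imputation"]["divisor_high"],
            )
    log = mx.log_transform(imputed)

    classifier = train(
        log,
        panel,
        seed=int(cfg["classifier"]["seed"]),
        n_trees=int(cfg["classifier"]["n_trees"]),
    )
    return SpeciesLibrary(
        linear=linear,
        log=log,
        manifest=manifest,
        informative=informative,
        panel=panel,
        classifier=classifier,
        min_normalized_abundance=m,
        seed=seed,
        config=cfg,
        metrics=metrics,
    )


def _collapse_replicates(
    tables: Mapping[str, pd.Series], manifest: pd.DataFrame
) -> tuple[dict[str, pd.Series], pd.DataFrame]:
    """Average replicate samples of each individual into one pseudo-sample."""
    new_tables: dict[str, pd.Series] = {}
    rows = []
    for (species, individual), grp in manifest.groupby(["species", "individual"]):
        sample_ids = [s for s in grp["sample_id"] if s in tables]
        if not sample_ids:
            continue
        merged = pd.concat([tables[s] for s in sample_ids], axis=1).mean(axis=1)
        sid = str(individual)
        new_tables[sid] = merged
        rows.append({"sample_id": sid, "species": species, "individual": individual})
    return new_tables, pd.DataFrame(rows)


# ----------------------------------------------------------------------
@dataclass
class SubmissionReport:
    species: str
    n_individuals: int
    per_individual_correlation: dict[str, float]
    passed: bool
    failures: list[str]
    warnings: list[str]
    qc_cutoff: float


def validate_submission(
    new_tables: Mapping[str, pd.Series],
    new_manifest: pd.DataFrame,
    library: SpeciesLibrary,
    config: Mapping[str, Any] | None = None,
) -> SubmissionReport:
    """QC a candidate new species before library expansion.

    Each individual's samples are correlated (leave-one-individual-out)
    against the remaining individuals of the submission over the
    informative peptides of the augmented matrix; every individual must
    exceed the QC cutoff (strict >, 0.7 by default).
    """
    cfg = deep_merge(library.config, config or {})
    cutoff = float(cfg["cutoffs"]["submission_qc"])
    new_manifest = new_manifest.reset_index(drop=True)
    validate_manifest(new_manifest, new_tables)
    species = sorted(new_manifest["species"].unique())
    if len(species) != 1:
        raise ValidationError(f"a submission must contain one species, got {species}")
    sp = species[0]
    if sp in library.species:
        raise ValidationError(f"species {sp!r} is already in the library")
    failures: list[str] = []
    warn_msgs = [
        f"recommended metadata column missing: {c}"
        for c in RECOMMENDED_METADATA
        if c not in new_manifest.columns
    ]
    n_ind = new_manifest["individual"].nunique()
    if n_ind < MIN_INDIVIDUALS:
        return SubmissionReport(
            species=sp,
            n_individuals=n_ind,
            per_individual_correlation={},
            passed=False,
            failures=[f"only {n_ind} individuals (need >= {MIN_INDIVIDUALS})"],
            warnings=warn_msgs,
            qc_cutoff=cutoff,
        )

    # augmented matrix: library's normalized columns + normalized submission
    combined_tables, combined_manifest = _combine_with_library(
        library, new_tables, new_manifest
    )
    raw = mx.AbundanceMatrix.from_tables(combined_tables, combined_manifest)
    linear = mx.normalize_total(raw)
    informative = select_informative(
        linear,
        presence_frac=cfg["informative"]["presence_frac"],
        variation_min=cfg["informative"]["variation_min"],
        variation_statistic=cfg["informative"]["variation_statistic"],
    )
    inf_rows = [p for p in informative if p in linear.values.index]
    if cfg["correlation"].get("missing_policy", "pairwise_complete") == "imputed":
        imputed = mx.impute_missing(
            linear,
            rng_seed=int(cfg["imputation"]["seed"]),
            divisor_low=cfg["imputation"]["divisor_low"],
            divisor_high=cfg["imputation"]["divisor_high"],
        )
        log_values = mx.log_transform(imputed).values
    else:
        with np.errstate(invalid="ignore"):
            log_values = np.log10(linear.values)  # NaN stays NaN
    log_inf = log_values.loc[inf_rows]
    log_species = linear.species

    sub_manifest = new_manifest.set_index("sample_id")
    per_individual: dict[str, float] = {}
    for individual, grp in sub_manifest.groupby("individual"):
        own = list(grp.index)
        others = [s for s in sub_manifest.index if s not in own]
        corrs = []
        for s in own:
            r = correlate_sample(
                log_inf[s],
                log_inf[others],
                log_species,
                method=cfg["correlation"]["method"],
                min_shared_peptides=cfg["correlation"]["min_shared_peptides"],
            )
            corrs.append(float(r.per_sample.mean()))
        per_individual[str(individual)] = float(np.mean(corrs))
    for individual, value in per_individual.items():
        if not value > cutoff:
            failures.append(
                f"individual {individual!r} within-species averaged correlation "
                f"{value:.3f} is not higher than {cutoff}"
            )
    return SubmissionReport(
        species=sp,
        n_individuals=n_ind,
        per_individual_correlation=per_individual,
        passed=not failures,
        failures=failures,
        warnings=warn_msgs,
        qc_cutoff=cutoff,
    )


def _combine_with_library(
    library: SpeciesLibrary,
    new_tables: Mapping[str, pd.Series],
    new_manifest: pd.DataFrame,
) -> tuple[dict[str, pd.Series], pd.DataFrame]:
    """Library columns (already normalized; normalization is idempotent) + new tables."""
    combined: dict[str, pd.Series] = {
        s: library.linear.values[s].dropna() for s in library.linear.values.columns
    }
    overlap = set(combined) & set(new_tables)
    if overlap:
        raise ValidationError(f"sample ids already in library: {sorted(overlap)[:5]}")
    for s, tab in new_tables.items():
        combined[s] = tab.dropna()
    combined_manifest = pd.concat(
        [library.manifest[list(MANIFEST_COLUMNS)],
         new_manifest[list(MANIFEST_COLUMNS)]],
        ignore_index=True,
    )
    return combined, combined_manifest


def add_species(
    library: SpeciesLibrary,
    new_tables: Mapping[str, pd.Series],
    new_manifest: pd.DataFrame,
    config: Mapping[str, Any] | None = None,
) -> SpeciesLibrary:
    """Rebuild the library with a validated new species added.

    The rebuild recomputes every metric (an existing peptide shared with
    the newcomer loses specificity 1 and drops out of the panels).  Builds
    are functional: any failure leaves the original library untouched.
    """
    report = validate_submission(new_tables, new_manifest, library, config)
    if not report.passed:
        raise ValidationError(
            f"submission for {report.species!r} failed QC: " + "; ".join(report.failures)
        )
    cfg = deep_merge(library.config, config or {})
    combined_tables, combined_manifest = _combine_with_library(
        library, new_tables, new_manifest
    )
    return build_library(combined_tables, combined_manifest, cfg)
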