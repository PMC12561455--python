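"""Reading and writing the tabular peptide-quantification dialect, the
sample manifest, and the on-disk species library.

Two table layouts are accepted:

* **long** — one row per (peptide, sample): a sample column plus one area
  column;
* **wide** — one row per peptide, one area column per sample (column named
  either after the sample directly or ``"Area <sample>"``).

Peptide identity is the full search-engine string including inline PTM
annotations (e.g. ``"GPP(+15.99)GK"``); it is preserved verbatim.  Blank,
NaN or zero areas are recorded as *missing*, never as 0 observations.
Column names are remappable because export headers vary between search
engine versions.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import joblib
import numpy as np
import pandas as pd

from .errors import (
    DuplicatePeptideError,
    FormatError,
    LibraryIntegrityError,
    LibraryVersionError,
)
from .library import MANIFEST_COLUMNS, SpeciesLibrary
from .matrix import SCALE_LOG10, SCALE_NORMALIZED, AbundanceMatrix
from .metrics import FeaturePanel

LIBRARY_FORMAT_VERSION = 1

_DIALECT_SEP = {"peaks_csv": ",", "generic_tsv": "\t"}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from logical fields to header names (configurable)."""

    peptide: str = "Peptide"
    accession: str = "Accession"
    mass: str = "Mass"
    rt: str = "RT"
    charge: str = "z"
    area: str = "Area"
    sample: str = "Sample"

    def meta_columns(self) -> tuple[str, ...]:
        return (self.peptide, self.accession, self.mass, self.rt, self.charge)


@dataclass(frozen=True)
class PeptideObservation:
    """One quantified peptide in one sample."""

    peptide_key: str
    sample_id: str
    accession: str | None
    mono_mass: float | None
    charge: int | None
    retention_time: float | None
    raw_abundance: float | None  # None = missing

    def __post_init__(self) -> None:
        if not self.peptide_key:
            raise FormatError("empty peptide key")
        if self.mono_mass is not None and not self.mono_mass > 0:
            raise FormatError(f"nonpositive mass for {self.peptide_key!r}")
        if self.charge is not None and self.charge < 1:
            raise FormatError(f"charge < 1 for {self.peptide_key!r}")


@dataclass
class PeptideTable:
    """Parsed quantification table: per-sample abundances plus peptide metadata."""

    abundances: dict[str, pd.Series]  # sample_id -> peptide_key -> abundance (NaN missing)
    metadata: pd.DataFrame  # index peptide_key; columns accession, mass, rt, charge
    observations: list[PeptideObservation] = field(default_factory=list, repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances)

    @property
    def peptides(self) -> list[str]:
        return list(self.metadata.index)


def _to_float(value) -> float:
    """Parse an area cell; blank/zero/unparseable -> NaN (missing)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    try:
        x = float(value)
    except (TypeError, ValueError):
        return np.nan
    return x if x > 0 else np.nan


def read_peptide_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    columns: ColumnMap | None = None,
) -> PeptideTable:
    """Parse a quantification table in long or wide layout.

    Raises :class:`FormatError` for an empty file or a header missing the
    peptide column, and :class:`DuplicatePeptideError` when a (peptide,
    sample) pair repeats.
    """
    if dialect not in _DIALECT_SEP:
        raise FormatError(f"unknown dialect {dialect!r}")
    columns = columns or ColumnMap()
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_DIALECT_SEP[dialect], dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path} is empty") from None
    if frame.empty and len(frame.columns) == 0:
        raise FormatError(f"{path} is empty")
    if columns.peptide not in frame.columns:
        raise FormatError(
            f"{path} header lacks required column {columns.peptide!r}"
        )
    frame[columns.peptide] = frame[columns.peptide].astype(str)

    long_layout = columns.sample in frame.columns
    if long_layout:
        if columns.area not in frame.columns:
            raise FormatError(f"{path} header lacks required column {columns.area!r}")
        return _parse_long(frame, columns)
    return _parse_wide(frame, columns)


def _meta_frame(frame: pd.DataFrame, columns: ColumnMap) -> pd.DataFrame:
    """First-occurrence peptide metadata."""
    meta = frame.drop_duplicates(subset=columns.peptide).set_index(columns.peptide)
    out = pd.DataFrame(index=meta.index)
    out.index.name = "peptide"
    for logical, name, caster in (
        ("accession", columns.accession, str),
        ("mass", columns.mass, float),
        ("rt", columns.rt, float),
        ("charge", columns.charge, float),
    ):
        if name in meta.columns:
            out[logical] = (
                pd.to_numeric(meta[name], errors="coerce")
                if caster is float
                else meta[name]
            )
        else:
            out[logical] = np.nan
    return out


def _build_observations(
    abundances: Mapping[str, pd.Series], metadata: pd.DataFrame
) -> list[PeptideObservation]:
    obs = []
    for sample, series in abundances.items():
        for pep, value in series.items():
            meta = metadata.loc[pep]
            mass = meta["mass"]
            charge = meta["charge"]
            rt = meta["rt"]
            obs.append(
                PeptideObservation(
                    peptide_key=str(pep),
                    sample_id=str(sample),
                    accession=None if pd.isna(meta["accession"]) else str(meta["accession"]),
                    mono_mass=None if pd.isna(mass) else float(mass),
                    charge=None if pd.isna(charge) else int(charge),
                    retention_time=None if pd.isna(rt) else float(rt),
                    raw_abundance=None if pd.isna(value) else float(value),
                )
            )
    return obs


def _parse_long(frame: pd.DataFrame, columns: ColumnMap) -> PeptideTable:
    pairs = frame[[columns.peptide, columns.sample]]
    dup = pairs.duplicated()
    if dup.any():
        raise DuplicatePeptideError(
            [tuple(row) for row in pairs[dup].itertuples(index=False)]
        )
    metadata = _meta_frame(frame, columns)
    abundances: dict[str, pd.Series] = {}
    for sample, grp in frame.groupby(columns.sample, sort=False):
        series = pd.Series(
            [_to_float(v) for v in grp[columns.area]],
            index=grp[columns.peptide].tolist(),
            dtype=float,
        )
        abundances[str(sample)] = series
    return PeptideTable(
        abundances=abundances,
        metadata=metadata,
        observations=_build_observations(abundances, metadata),
    )


def _parse_wide(frame: pd.DataFrame, columns: ColumnMap) -> PeptideTable:
    dup = frame[columns.peptide].duplicated()
    if dup.any():
        raise DuplicatePeptideError(
            [(p, "<all samples>") for p in frame[columns.peptide][dup]]
        )
    meta_cols = [c for c in columns.meta_columns() if c in frame.columns]
    sample_cols = [c for c in frame.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError("wide table has no per-sample area columns")
    metadata = _meta_frame(frame, columns)
    prefix = columns.area + " "
    abundances: dict[str, pd.Series] = {}
    for col in sample_cols:
        sample = col[len(prefix):] if col.startswith(prefix) else col
        abundances[sample] = pd.Series(
            [_to_float(v) for v in frame[col]],
            index=frame[columns.peptide].tolist(),
            dtype=float,
        )
    return PeptideTable(
        abundances=abundances,
        metadata=metadata,
        observations=_build_observations(abundances, metadata),
    )


def write_peptide_table(
    table: PeptideTable,
    path: str | Path,
    dialect: str = "generic_tsv",
    columns: ColumnMap | None = None,
) -> None:
    """Write a table in long layout (round-trips with :func:`read_peptide_table`)."""
    if dialect not in _DIALECT_SEP:
        raise FormatError(f"unknown dialect {dialect!r}")
    columns = columns or ColumnMap()
    rows = []
    for sample, series in table.abundances.items():
        for pep, value in series.items():
            meta = table.metadata.loc[pep]
            rows.append(
                {
                    columns.peptide: pep,
                    columns.accession: meta["accession"],
                    columns.mass: meta["mass"],
                    columns.rt: meta["rt"],
                    columns.charge: meta["charge"],
                    columns.sample: sample,
                    columns.area: "" if pd.isna(value) else repr(float(value)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_DIALECT_SEP[dialect], index=False)


# ----------------------------------------------------------------------
def read_manifest(path: str | Path) -> pd.DataFrame:
    """Sample manifest CSV with sample_id, species, individual columns."""
    try:
        manifest = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path} is empty") from None
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest {path} lacks column(s): {missing}")
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


# ----------------------------------------------------------------------
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _matrix_to_csv(matrix: AbundanceMatrix, path: Path) -> None:
    matrix.values.rename_axis("peptide").to_csv(path, float_format="%.17g")


def _matrix_from_csv(
    path: Path, manifest: pd.DataFrame, scale: str, mask: pd.DataFrame | None = None
) -> AbundanceMatrix:
    values = pd.read_csv(path, index_col="peptide", float_precision="round_trip")
    man = manifest.set_index("sample_id")
    return AbundanceMatrix(
        values=values,
        missing_mask=mask if mask is not None else values.isna(),
        species=man.loc[values.columns, "species"],
        individuals=man.loc[values.columns, "individual"],
        scale=scale,
        imputed=mask is not None,
    )


def write_library(library: SpeciesLibrary, path: str | Path) -> None:
    """Serialize a library to a directory (JSON metadata + CSV matrices +
    a joblib classifier artifact), with per-file checksums for integrity."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "manifest": "manifest.csv",
        "linear": "linear.csv",
        "log": "log.csv",
        "forest": "forest.joblib",
    }
    library.manifest.to_csv(out / files["manifest"], index=False)
    _matrix_to_csv(library.linear, out / files["linear"])
    _matrix_to_csv(library.log, out / files["log"])
    joblib.dump(library.classifier.model, out / files["forest"], compress=3)
    meta = {
        "format_version": LIBRARY_FORMAT_VERSION,
        "species": library.species,
        "informative": library.informative,
        "panel": {
            "per_species": library.panel.per_species,
            "n_top": library.panel.n_top,
        },
        "classifier": {
            "feature_order": library.classifier.feature_order,
            "species_classes": library.classifier.species_classes,
            "seed": library.classifier.seed,
            "n_trees": library.classifier.n_trees,
            "oob_error": library.classifier.oob_error,
        },
        "min_normalized_abundance": library.min_normalized_abundance,
        "seed": library.seed,
        "config": library.config,
        "content_hash": library.content_hash(),
        "checksums": {name: _sha256(out / fname) for name, fname in files.items()},
        "files": files,
    }
    (out / "library.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_library(path: str | Path) -> SpeciesLibrary:
    """Load a serialized library, verifying format version and checksums."""
    root = Path(path)
    meta_path = root / "library.json"
    if not meta_path.exists():
        raise LibraryIntegrityError(f"{root} contains no library.json")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise LibraryIntegrityError(f"library.json is corrupt: {exc}") from None
    version = meta.get("format_version")
    if version != LIBRARY_FORMAT_VERSION:
        raise LibraryVersionError(
            f"library format version {version!r} is not supported "
            f"(expected {LIBRARY_FORMAT_VERSION})"
        )
    files = meta["files"]
    for name, fname in files.items():
        fpath = root / fname
        if not fpath.exists():
            raise LibraryIntegrityError(f"missing library file {fname}")
        if _sha256(fpath) != meta["checksums"][name]:
            raise LibraryIntegrityError(f"checksum mismatch for {fname} (truncated?)")

    from .forest import ClassifierState  # deferred: keep io importable standalone

    manifest = pd.read_csv(root / files["manifest"], dtype=str)
    linear = _matrix_from_csv(root / files["linear"], manifest, SCALE_NORMALIZED)
    log = _matrix_from_csv(root / files["log"], manifest, SCALE_LOG10)
    log.missing_mask = (
        linear.missing_mask.reindex(log.values.index).fillna(False).astype(bool)
    )
    log.imputed = True
    model = joblib.load(root / files["forest"])
    classifier = ClassifierState(
        feature_order=list(meta["classifier"]["feature_order"]),
        species_classes=list(meta["classifier"]["species_classes"]),
        model=model,
        seed=int(meta["classifier"]["seed"]),
        n_trees=int(meta["classifier"]["n_trees"]),
        oob_error=meta["classifier"]["oob_error"],
    )
    panel = FeaturePanel(
        per_species={k: list(v) for k, v in meta["panel"]["per_species"].items()},
        n_top=int(meta["panel"]["n_top"]),
    )
    return SpeciesLibrary(
        linear=linear,
        log=log,
        manifest=manifest,
        informative=list(meta["informative"]),
        panel=panel,
        classifier=classifier,
        min_normalized_abundance=float(meta["min_normalized_abundance"]),
        seed=int(meta["seed"]),
        config=meta["config"],
    )
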