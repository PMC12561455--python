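"""Ground-truth synthetic multi-species peptide libraries.

The generator emulates the statistical structure the identification model
assumes: every species carries a pool of private (species-specific)
peptides, sister-species pairs share a lineage pool, and a universal pool
is observed everywhere but with species-dependent abundance offsets.  Log10
abundances are baseline-plus-noise Gaussian (i.e. log-normal areas), and
missingness is Bernoulli per (peptide, sample) with per-class detection
probabilities.  Fixed seeds give byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

_AMINO_ACIDS = "GPASTKRDEQNVLIFM"
_PTM_TAGS = ["", "", "", "(+15.99)", "(+.98)", "(+16.00)"]


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic library generator."""

    n_species: int = 8
    individuals_per_species: int = 3
    replicates: int = 1
    n_specific_per_species: int = 20
    n_shared_lineage: int = 10
    n_universal: int = 60
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 0.6
    species_offset_sd: float = 2.0  # between-species spread of shared peptides
    within_noise_sd: float = 0.15  # per-sample log10 noise
    detect_specific: float = 1.0
    detect_shared: float = 0.9
    detect_universal: float = 0.9
    mass_low: float = 800.0
    mass_high: float = 3500.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("detect_specific", "detect_shared", "detect_universal"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        for name in ("baseline_log_sd", "species_offset_sd", "within_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_species < 1 or self.individuals_per_species < 3:
            raise ValidationError(
                "need n_species >= 1 and individuals_per_species >= 3"
            )
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not 0 < self.mass_low < self.mass_high:
            raise ValidationError("mass range must satisfy 0 < low < high")


@dataclass
class PeptideTruth:
    peptide_key: str
    peptide_class: str  # "specific" | "shared" | "universal"
    species: list[str]  # species in which the peptide can be observed
    baseline_log10: float
    offsets_log10: dict[str, float]
    detection_prob: float
    mono_mass: float


@dataclass
class SimulatedLibrary:
    config: GeneratorConfig
    tables: dict[str, pd.Series]  # sample_id -> raw abundances
    manifest: pd.DataFrame
    metadata: pd.DataFrame  # peptide -> accession, mass, rt, charge
    truth: dict[str, PeptideTruth] = field(repr=False, default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted(self.manifest["species"].unique())

    def specific_peptides(self, species: str) -> list[str]:
        return sorted(
            k
            for k, t in self.truth.items()
            if t.peptide_class == "specific" and t.species == [species]
        )


def _unique_key(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 17))
        seq = "".join(rng.choice(list(_AMINO_ACIDS), size=length))
        tag = _PTM_TAGS[int(rng.integers(0, len(_PTM_TAGS)))]
        if tag:
            pos = int(rng.integers(1, length))
            seq = seq[:pos] + tag + seq[pos:]
        if seq not in used:
            used.add(seq)
            return seq


def _species_names(n: int) -> list[str]:
    return [f"species{idx + 1:02d}" for idx in range(n)]


def generate_library(config: GeneratorConfig) -> SimulatedLibrary:
    """Draw a full labeled library in the quantification-table dialect."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = _species_names(config.n_species)
    used: set[str] = set()
    truth: dict[str, PeptideTruth] = {}

    def add_peptide(cls: str, members: list[str], detect: float, offsets=None) -> None:
        key = _unique_key(rng, used)
        baseline = float(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
        if offsets is None:
            offsets = {
                sp: float(rng.normal(0.0, config.species_offset_sd)) for sp in members
            }
        truth[key] = PeptideTruth(
            peptide_key=key,
            peptide_class=cls,
            species=list(members),
            baseline_log10=baseline,
            offsets_log10=offsets,
            detection_prob=detect,
            mono_mass=float(rng.uniform(config.mass_low, config.mass_high)),
        )

    for sp in species:
        for _ in range(config.n_specific_per_species):
            add_peptide("specific", [sp], config.detect_specific, offsets={sp: 0.0})
    # sister pairs: (1,2), (3,4), ... share a lineage pool
    for i in range(0, config.n_species - 1, 2):
        pair = [species[i], species[i + 1]]
        for _ in range(config.n_shared_lineage):
            add_peptide("shared", pair, config.detect_shared)
    for _ in range(config.n_universal):
        add_peptide("universal", list(species), config.detect_universal)

    manifest_rows = []
    tables: dict[str, pd.Series] = {}
    keys = list(truth)
    for sp in species:
        for ind in range(1, config.individuals_per_species + 1):
            individual = f"{sp}_ind{ind}"
            for rep in range(1, config.replicates + 1):
                sample = individual if config.replicates == 1 else f"{individual}_r{rep}"
                manifest_rows.append(
                    {"sample_id": sample, "species": sp, "individual": individual}
                )
                tables[sample] = _draw_sample(rng, truth, keys, sp, config)
    manifest = pd.DataFrame(manifest_rows)
    metadata = pd.DataFrame(
        {
            "accession": ["COL1A1_SYN"] * len(keys),
            "mass": [truth[k].mono_mass for k in keys],
            "rt": np.round(rng.uniform(5.0, 70.0, size=len(keys)), 2),
            "charge": rng.integers(2, 5, size=len(keys)),
        },
        index=pd.Index(keys, name="peptide"),
    )
    return SimulatedLibrary(
        config=config, tables=tables, manifest=manifest, metadata=metadata, truth=truth
    )


def _draw_sample(
    rng: np.random.Generator,
    truth: dict[str, PeptideTruth],
    keys: list[str],
    species: str,
    config: GeneratorConfig,
    offsets_override: dict[str, dict[str, float]] | None = None,
    dropped: set[str] | None = None,
) -> pd.Series:
    values = {}
    for key in keys:
        t = truth[key]
        if species not in t.species and offsets_override is None:
            continue
        if dropped and key in dropped:
            continue
        if rng.random() >= t.detection_prob:
            continue
        if offsets_override is not None:
            if key not in offsets_override:
                continue
            offset = offsets_override[key].get(species, 0.0)
        else:
            offset = t.offsets_log10.get(species, 0.0)
        log_abund = t.baseline_log10 + offset + rng.normal(0.0, config.within_noise_sd)
        values[key] = 10.0**log_abund
    return pd.Series(values, dtype=float).sort_index()


def generate_query(
    sim: SimulatedLibrary,
    species: str,
    seed: int,
    divergence: float = 1.0,
    base_species: str | None = None,
) -> pd.Series:
    """One unlabeled query sample.

    ``species`` is a library species name, or ``"novel"`` for a species
    absent from the library.  A novel query reuses a base species' profile:
    a ``divergence`` fraction of the base's private peptides is dropped,
    shared/universal abundance offsets are blended with fresh draws in the
    same proportion, and a private pool of brand-new peptides is added.
    ``divergence=1`` is a fully unrelated species; small values emulate a
    close sister taxon.
    """
    rng = np.random.default_rng(seed)
    keys = list(sim.truth)
    config = sim.config
    if species != "novel":
        if species not in sim.species:
            raise DataError(f"unknown species {species!r}")
        return _draw_sample(rng, sim.truth, keys, species, config)

    if not 0.0 <= divergence <= 1.0:
        raise ValidationError("divergence must lie in [0, 1]")
    base = base_species or sim.species[0]
    if base not in sim.species:
        raise DataError(f"unknown base species {base!r}")

    base_specific = sim.specific_peptides(base)
    n_drop = int(round(divergence * len(base_specific)))
    dropped = set(
        rng.choice(base_specific, size=n_drop, replace=False).tolist()
        if n_drop
        else []
    )
    offsets: dict[str, dict[str, float]] = {}
    for key, t in sim.truth.items():
        if t.peptide_class == "specific":
            if t.species == [base] and key not in dropped:
                offsets[key] = {base: 0.0}
            continue
        if base not in t.species:
            continue  # other lineages' shared pool stays unobserved
        old = t.offsets_log10.get(base, 0.0)
        fresh = rng.normal(0.0, config.species_offset_sd)
        offsets[key] = {base: (1.0 - divergence) * old + divergence * float(fresh)}
    query = _draw_sample(
        rng, sim.truth, keys, base, config, offsets_override=offsets
    )

    used = set(sim.truth)
    novel = {}
    for _ in range(config.n_specific_per_species):
        key = _unique_key(rng, used)
        log_abund = rng.normal(config.baseline_log_mean, config.baseline_log_sd)
        novel[key] = 10.0 ** (log_abund + rng.normal(0.0, config.within_noise_sd))
    return pd.concat([query, pd.Series(novel, dtype=float)]).sort_index()


# ----------------------------------------------------------------------
def write_simulation(sim: SimulatedLibrary, out_dir: str | Path) -> None:
    """Write tables.tsv (long layout), manifest.csv and ground_truth.json."""
    from .io import PeptideTable, write_manifest, write_peptide_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = PeptideTable(abundances=sim.tables, metadata=sim.metadata)
    write_peptide_table(table, out / "tables.tsv", dialect="generic_tsv")
    write_manifest(sim.manifest, out / "manifest.csv")
    truth = {
        "config": asdict(sim.config),
        "peptides": {
            k: {
                "class": t.peptide_class,
                "species": t.species,
                "baseline_log10": t.baseline_log10,
                "offsets_log10": t.offsets_log10,
                "detection_prob": t.detection_prob,
                "mono_mass": t.mono_mass,
            }
            for k, t in sim.truth.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
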