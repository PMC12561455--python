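# kisse

Species identification from bone-collagen tandem-MS peptide quantification
tables. Given per-sample peptide abundance tables (PEAKS-Studio-style
exports, long or wide layout) and a sample manifest, `kisse` builds a
species library — total-abundance normalization, log10 transform,
minimum-anchored stochastic imputation of missing values, per-peptide
Specificity / Sensitivity / Exclusivity metrics, a per-species top-11
species-specific feature panel, and a random-forest classifier — and
identifies query samples by combining classifier probabilities with
per-species averaged abundance correlations into a normalized prediction
score. Samples whose best averaged correlation falls below a cutoff
(default 0.6) are flagged as *not in the database* and reported with the
closest library species instead. A ppm mass-collision analysis quantifies
which species remain identifiable by peptide-mass fingerprinting alone.

## CLI

```bash
# generate a ground-truth synthetic library (tables.tsv, manifest.csv, ground_truth.json)
kisse simulate --out sim/ --seed 1

# build a species library (every species needs >= 3 individuals and >= 11
# species-specific peptides)
kisse build sim/tables.tsv sim/manifest.csv --out lib/

# identify query samples: per-sample TSV score table + JSON verdict
kisse predict lib/ query.tsv --out report/

# QC a new-species submission (leave-one-individual-out correlation > 0.7)
kisse validate lib/ new_tables.tsv new_manifest.csv

# rebuild the library with a validated new species (all metrics recomputed)
kisse add-species lib/ new_tables.tsv new_manifest.csv --out lib_v2/

# mass-collision analysis among species-specific peptides
kisse ppm lib/ --masses markers.tsv --tolerance 20 --min-markers 9 --out ppm/
```

All subcommands accept `--config config.yaml` to override defaults
(imputation divisors and seed, informative-peptide thresholds, panel size,
forest size, correlation method and missingness policy, cutoffs); every run
writes a `resolved_config.json` snapshot next to its outputs.

Input tables need a `Peptide` column plus either a `Sample`/`Area` pair
(long layout) or one area column per sample (wide layout); `Accession`,
`Mass`, `RT`, `z` are carried through when present, and all column names
are remappable. Peptide identity is the verbatim search-engine string
including PTM annotations. Blank or zero areas are treated as missing,
never as zero abundance. The manifest is a CSV with `sample_id`, `species`,
`individual` columns.

## Layout

- `src/kisse/io.py` — table/manifest parsing, library (de)serialization
- `src/kisse/matrix.py` — abundance matrices: normalize, impute, log10
- `src/kisse/metrics.py` — Specificity/Sensitivity/Exclusivity, informative
  set, feature panel
- `src/kisse/forest.py` — random-forest classifier (OOB-evaluated)
- `src/kisse/correlation.py` — per-sample correlations, species averages,
  Welch t-test
- `src/kisse/prediction.py` — score combination, in-database decision,
  reports
- `src/kisse/library.py` — library build / submission QC / expansion
- `src/kisse/collisions.py` — ppm mass-collision analysis
- `src/kisse/simulate.py` — ground-truth synthetic data generator
- `src/kisse/cli.py` — command-line interface
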