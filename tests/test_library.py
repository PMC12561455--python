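from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from kisse import add_species, build_library, validate_submission
from kisse.errors import ValidationError
from kisse.metrics import compute_metrics
from kisse.matrix import AbundanceMatrix, normalize_total
from kisse.simulate import GeneratorConfig, generate_library


def _species_tables(sim, species):
    manifest = sim.manifest[sim.manifest["species"] == species].reset_index(drop=True)
    tables = {s: sim.tables[s] for s in manifest["sample_id"]}
    return tables, manifest


class TestBuildLibrary:
    def test_panel_union_size(self, lib8):
        assert len(lib8.classifier.feature_order) == 8 * 11

    def test_two_individual_species_rejected_by_name(self, sim3):
        manifest = sim3.manifest.copy()
        drop = manifest[
            (manifest["species"] == "species02")
            & (manifest["individual"] == "species02_ind3")
        ]["sample_id"]
        manifest = manifest[~manifest["sample_id"].isin(drop)]
        tables = {s: sim3.tables[s] for s in manifest["sample_id"]}
        with pytest.raises(ValidationError, match="species02"):
            build_library(tables, manifest)

    def test_rebuild_same_seed_same_hash(self, sim3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = build_library(sim3.tables, sim3.manifest)
            b = build_library(sim3.tables, sim3.manifest)
        assert a.content_hash() == b.content_hash()

    def test_average_replicates_mode(self):
        sim = generate_library(
            GeneratorConfig(
                n_species=3, n_specific_per_species=14, n_shared_lineage=4,
                n_universal=24, replicates=2, seed=33,
            )
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lib = build_library(sim.tables, sim.manifest, average_replicates=True)
        # one pseudo-sample per individual
        assert lib.linear.n_samples == 3 * 3


class TestValidateSubmission:
    def test_coherent_submission_passes(self, sim8, lib3, sim3):
        # species04 from the 8-species world is unknown to the 3-species library
        sim = generate_library(
            GeneratorConfig(n_species=4, n_specific_per_species=14,
                            n_shared_lineage=4, n_universal=30, seed=44)
        )
        tables, manifest = _species_tables(sim, "species04")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = validate_submission(tables, manifest, lib3)
        assert report.passed
        assert all(v > 0.7 for v in report.per_individual_correlation.values())
        assert any("bone_element" in w for w in report.warnings)

    def test_too_few_individuals_rejected(self, lib3):
        sim = generate_library(
            GeneratorConfig(n_species=4, n_specific_per_species=14,
                            n_shared_lineage=4, n_universal=30, seed=45)
        )
        tables, manifest = _species_tables(sim, "species04")
        keep = manifest["individual"].isin(
            ["species04_ind1", "species04_ind2"]
        )
        manifest = manifest[keep]
        tables = {s: tables[s] for s in manifest["sample_id"]}
        report = validate_submission(tables, manifest, lib3)
        assert not report.passed
        assert "individuals" in report.failures[0]

    def test_planted_outlier_rejected_by_name(self, lib3):
        sim = generate_library(
            GeneratorConfig(n_species=5, n_specific_per_species=14,
                            n_shared_lineage=4, n_universal=30, seed=46)
        )
        tables, manifest = _species_tables(sim, "species04")
        # swap one individual's sample for a different species' profile
        outlier_sample = manifest["sample_id"].iloc[0]
        donor = sim.manifest[sim.manifest["species"] == "species05"]["sample_id"].iloc[0]
        tables = dict(tables)
        tables[outlier_sample] = sim.tables[donor]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = validate_submission(tables, manifest, lib3)
        assert not report.passed
        assert any("species04_ind1" in f for f in report.failures)

    def test_boundary_is_strictly_greater_than(self, lib3):
        """An averaged correlation exactly at the cutoff is rejected."""
        sim = generate_library(
            GeneratorConfig(n_species=4, n_specific_per_species=14,
                            n_shared_lineage=4, n_universal=30,
                            within_noise_sd=0.0, detect_shared=1.0,
                            detect_universal=1.0, seed=47)
        )
        tables, manifest = _species_tables(sim, "species04")
        # noise-free draws from one profile correlate exactly 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = validate_submission(
                tables, manifest, lib3, config={"cutoffs": {"submission_qc": 1.0}}
            )
        assert not report.passed

    def test_existing_species_rejected(self, lib3, sim3):
        tables, manifest = _species_tables(sim3, "species01")
        with pytest.raises(ValidationError, match="already in the library"):
            validate_submission(tables, manifest, lib3)


@pytest.fixture(scope="module")
def sim4():
    return generate_library(
        GeneratorConfig(n_species=4, n_specific_per_species=14,
                        n_shared_lineage=4, n_universal=30, seed=48)
    )


class TestAddSpecies:

    def test_distant_species_extends_panel(self, lib3, sim4):
        tables, manifest = _species_tables(sim4, "species04")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rebuilt = add_species(lib3, tables, manifest)
        n_top = lib3.panel.n_top
        assert len(rebuilt.classifier.feature_order) == 4 * n_top
        assert "species04" in rebuilt.species

    def test_specificity_erosion_is_monotone(self, lib3, sim4):
        tables, manifest = _species_tables(sim4, "species04")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rebuilt = add_species(lib3, tables, manifest)
        before = lib3.metrics
        after = rebuilt.metrics
        shared_peptides = before.specificity.index.intersection(
            after.specificity.index
        )
        for pep in shared_peptides:
            s_before = before.specificity[pep]
            s_after = after.specificity[pep]
            if np.isnan(s_before) or np.isnan(s_after):
                continue
            assert s_after <= s_before + 1e-12

    def test_shared_specific_peptide_leaves_both_panels(self, lib3, sim3, sim4):
        """A newcomer observing an existing 'specific' peptide erodes it."""
        tables, manifest = _species_tables(sim4, "species04")
        victim = lib3.panel.per_species["species01"][0]
        tables = {s: t.copy() for s, t in tables.items()}
        for s in tables:
            tables[s].loc[victim] = 5e5  # newcomer now expresses the peptide
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rebuilt = add_species(lib3, tables, manifest)
        assert rebuilt.metrics.specificity[victim] == pytest.approx(0.5)
        for sp, peps in rebuilt.panel.per_species.items():
            assert victim not in peps

    def test_failed_rebuild_leaves_original_untouched(self, lib3, sim4):
        tables, manifest = _species_tables(sim4, "species04")
        before = lib3.content_hash()
        bad_manifest = manifest.iloc[:1]  # one individual -> QC failure
        bad_tables = {s: tables[s] for s in bad_manifest["sample_id"]}
        with pytest.raises(ValidationError):
            add_species(lib3, bad_tables, bad_manifest)
        assert lib3.content_hash() == before

    def test_incremental_equals_scratch(self, lib3, sim3, sim4):
        tables, manifest = _species_tables(sim4, "species04")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            incremental = add_species(lib3, tables, manifest)
            all_tables = dict(sim3.tables)
            all_tables.update(tables)
            all_manifest = pd.concat(
                [sim3.manifest, manifest], ignore_index=True
            )
            scratch = build_library(all_tables, all_manifest, lib3.config)
        assert incremental.content_hash() == scratch.content_hash()
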