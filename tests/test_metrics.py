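from __future__ import annotations

import numpy as np
import pytest

from conftest import make_matrix
from kisse.errors import DataError, InsufficientDataError
from kisse.metrics import (
    build_feature_panel,
    compute_exclusivity,
    compute_metrics,
    compute_sensitivity,
    compute_specificity,
    select_informative,
)
from oracles import brute_exclusivity, brute_sensitivity, brute_specificity


def eight_species_matrix(n_found: int):
    """One peptide 'q' observed in the first n_found of 8 single-sample species."""
    manifest = [(f"s{i}", f"sp{i}", f"i{i}") for i in range(8)]
    values = {"q": {f"s{i}": (0.5 if i < n_found else None) for i in range(8)}}
    values["filler"] = {f"s{i}": 0.5 for i in range(8)}
    return make_matrix(values, manifest)


class TestSpecificity:
    @pytest.mark.parametrize("n_found,expected", [(1, 1.0), (4, 0.25), (8, 0.125)])
    def test_one_over_n(self, n_found, expected):
        assert compute_specificity("q", eight_species_matrix(n_found)) == expected

    def test_never_observed_is_error(self):
        m = make_matrix(
            {"q": {"s1": None}, "p": {"s1": 1.0}}, [("s1", "A", "a1")]
        )
        with pytest.raises(DataError, match="never observed"):
            compute_specificity("q", m)


class TestSensitivity:
    def test_all_individuals(self):
        manifest = [(f"s{i}", "seal", f"ind{i}") for i in range(9)]
        m = make_matrix({"q": {f"s{i}": 0.1 for i in range(9)}}, manifest)
        assert compute_sensitivity("q", "seal", m) == 1.0

    def test_two_of_three(self):
        manifest = [(f"s{i}", "A", f"ind{i}") for i in range(3)]
        m = make_matrix(
            {"q": {"s0": 0.1, "s1": 0.1, "s2": None}, "p": {"s2": 0.5}}, manifest
        )
        assert compute_sensitivity("q", "A", m) == pytest.approx(2 / 3)

    def test_absent_species_is_zero(self):
        manifest = [("s0", "A", "a"), ("s1", "B", "b")]
        m = make_matrix({"q": {"s0": 0.1, "s1": None}, "p": {"s1": 0.5}}, manifest)
        assert compute_sensitivity("q", "B", m) == 0.0

    def test_replicates_collapse_by_presence_or(self):
        manifest = [("r1", "A", "ind1"), ("r2", "A", "ind1"), ("r3", "A", "ind2")]
        m = make_matrix(
            {"q": {"r1": 0.1, "r2": None, "r3": None}, "p": {"r2": 1.0, "r3": 1.0}},
            manifest,
        )
        # ind1 observed (via r1), ind2 not -> 1/2
        assert compute_sensitivity("q", "A", m) == pytest.approx(0.5)

    def test_unknown_species_is_error(self):
        m = make_matrix({"q": {"s1": 0.1}}, [("s1", "A", "a1")])
        with pytest.raises(DataError, match="unknown species"):
            compute_sensitivity("q", "Z", m)


class TestExclusivity:
    def test_private_peptide_hand_value(self):
        manifest = [("a1", "A", "a1"), ("a2", "A", "a2"), ("b1", "B", "b1")]
        m = make_matrix(
            {"q": {"a1": 0.1, "a2": 0.1, "b1": None}, "p": {"b1": 0.3}}, manifest
        )
        # (0.1+0.1)^2 / 0.2 = 0.2
        assert compute_exclusivity("q", "A", m) == pytest.approx(0.2)
        assert compute_exclusivity("q", "B", m) == 0.0

    def test_split_peptide_scores_below_private(self):
        manifest = [("a1", "A", "a1"), ("b1", "B", "b1")]
        m = make_matrix({"q": {"a1": 0.1, "b1": 0.1}}, manifest)
        # each species: 0.01/0.2 = 0.05 < 0.2 (the private case)
        assert compute_exclusivity("q", "A", m) == pytest.approx(0.05)
        assert compute_exclusivity("q", "B", m) == pytest.approx(0.05)

    def test_unquantified_everywhere_warns_zero(self):
        manifest = [("a1", "A", "a1")]
        m = make_matrix({"q": {"a1": None}, "p": {"a1": 1.0}}, manifest)
        with pytest.warns(UserWarning):
            assert compute_exclusivity("q", "A", m) == 0.0


class TestOracleEquivalence:
    """All three metrics against loop-and-dict brute force on random matrices."""

    @pytest.mark.parametrize("trial", range(25))
    def test_random_small_matrices(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_species = int(rng.integers(2, 5))
        manifest, species_of, individual_of = [], {}, {}
        for sp in range(n_species):
            for ind in range(int(rng.integers(1, 4))):
                sid = f"sp{sp}_i{ind}"
                manifest.append((sid, f"sp{sp}", f"sp{sp}_ind{ind}"))
                species_of[sid] = f"sp{sp}"
                individual_of[sid] = f"sp{sp}_ind{ind}"
        samples = [row[0] for row in manifest]
        n_peptides = int(rng.integers(2, 21))
        values, cells = {}, {}
        for p in range(n_peptides):
            pep = f"pep{p:02d}"
            values[pep] = {}
            for s in samples:
                if rng.random() < 0.35:
                    values[pep][s] = None
                    cells[(pep, s)] = None
                else:
                    v = float(rng.uniform(0.001, 1.0))
                    values[pep][s] = v
                    cells[(pep, s)] = v
        m = make_matrix(values, manifest)
        metrics = compute_metrics(m)
        for pep in values:
            observed = any(v is not None for (p, s), v in cells.items() if p == pep)
            if observed:
                assert compute_specificity(pep, m) == brute_specificity(
                    cells, species_of, pep
                )
                assert metrics.specificity[pep] == brute_specificity(
                    cells, species_of, pep
                )
            for sp in sorted({v for v in species_of.values()}):
                assert compute_sensitivity(pep, sp, m) == pytest.approx(
                    brute_sensitivity(cells, species_of, individual_of, pep, sp)
                )
                assert metrics.sensitivity.loc[pep, sp] == pytest.approx(
                    brute_sensitivity(cells, species_of, individual_of, pep, sp)
                )
                assert metrics.exclusivity.loc[pep, sp] == pytest.approx(
                    brute_exclusivity(cells, species_of, pep, sp), abs=1e-15
                )

    def test_specificity_times_n_is_one(self, lib8):
        metrics = lib8.metrics
        observed = metrics.n_species_found > 0
        product = metrics.specificity[observed] * metrics.n_species_found[observed]
        assert np.allclose(product, 1.0)


class TestSelectInformative:
    def test_flat_peptide_excluded(self):
        manifest = [("a1", "A", "a1"), ("b1", "B", "b1"), ("c1", "C", "c1")]
        m = make_matrix({"flat": {"a1": 0.5, "b1": 0.5, "c1": 0.5},
                         "other": {"a1": 0.5, "b1": 0.5, "c1": 0.5}}, manifest)
        assert select_informative(m) == []

    def test_species_specific_included_regardless_of_presence(self):
        manifest = [(f"s{i}", f"sp{i % 4}", f"i{i}") for i in range(8)]
        values = {"rare": {"s0": 0.2, "s4": 0.3}}  # only sp0, both its individuals
        values["bg"] = {f"s{i}": 0.5 for i in range(8)}
        m = make_matrix(values, manifest)
        assert "rare" in select_informative(m, presence_frac=0.9)

    def test_planted_informative_recovered_exactly(self, sim8):
        """Generator ground truth: specific + offset-variable peptides in, nothing else."""
        from kisse.matrix import normalize_total
        from kisse.matrix import AbundanceMatrix

        raw = AbundanceMatrix.from_tables(sim8.tables, sim8.manifest)
        linear = normalize_total(raw)
        informative = set(select_informative(linear))
        specific = {
            k for k, t in sim8.truth.items() if t.peptide_class == "specific"
        }
        detected_specific = {
            k for k in specific if not linear.values.loc[k].isna().all()
        }
        assert detected_specific <= informative
        # everything selected is either planted-specific or genuinely variable
        for pep in informative - specific:
            assert sim8.truth[pep].peptide_class in ("shared", "universal")


class TestFeaturePanel:
    def test_three_species_union_of_six(self):
        manifest = []
        values = {}
        for sp in range(3):
            for ind in range(2):
                manifest.append((f"sp{sp}_i{ind}", f"sp{sp}", f"sp{sp}_ind{ind}"))
        for sp in range(3):
            for p in range(3):
                pep = f"sp{sp}_pep{p}"
                values[pep] = {
                    f"sp{s}_i{i}": (0.1 * (p + 1) if s == sp else None)
                    for s in range(3)
                    for i in range(2)
                }
        m = make_matrix(values, manifest)
        panel = build_feature_panel(m, n_top=2)
        assert len(panel.feature_order) == 6
        # highest exclusivity first: pep2 (largest abundance) then pep1
        assert panel.per_species["sp0"] == ["sp0_pep2", "sp0_pep1"]

    def test_insufficient_species_named_in_error(self):
        manifest = [("a1", "A", "a1"), ("b1", "B", "b1")]
        values = {
            "a_pep": {"a1": 0.5, "b1": None},
            "b_pep": {"a1": None, "b1": 0.5},
        }
        m = make_matrix(values, manifest)
        with pytest.raises(InsufficientDataError, match="'A' has only 1"):
            build_feature_panel(m, n_top=2)

    def test_tie_break_is_deterministic(self):
        manifest = [("a1", "A", "a1"), ("b1", "B", "b1")]
        values = {
            "zz_pep": {"a1": 0.25, "b1": None},
            "aa_pep": {"a1": 0.25, "b1": None},
            "b_pep": {"a1": None, "b1": 0.5},
        }
        m = make_matrix(values, manifest)
        panel1 = build_feature_panel(m, n_top=1)
        panel2 = build_feature_panel(m, n_top=1)
        assert panel1.per_species["A"] == ["aa_pep"]  # lexical on equal exclusivity
        assert panel1.per_species == panel2.per_species

    def test_exclusivity_sum_bounded_by_total(self, lib8):
        metrics = lib8.metrics
        totals = lib8.linear.observed_values().sum(axis=1)
        sums = metrics.exclusivity.sum(axis=1)
        assert (sums <= totals + 1e-12).all()
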