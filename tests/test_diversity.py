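"""U/T beta-diversity, Shannon index, unknown-diversity and frequency tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from micromiss import diversity
from micromiss.diversity import UTResult, shannon_index, taxon_frequency_table, unknown_diversity, ut_ratio
from micromiss.tables_io import (
    DetectionMatrix,
    SpeciesCatalog,
    SpeciesRecord,
    ValidationError,
    load_missing_repertoire_catalog,
    load_new_taxa,
    load_new_taxa_catalog,
)

from conftest import make_matrix


class TestUTRatio:
    def test_no_unique_species(self):
        m = make_matrix(
            {"s1": {"A": True, "B": True}, "s2": {"A": True, "B": True}},
            {"s1": "case", "s2": "case", },
        )
        r = ut_ratio(m, "case")
        assert (r.unique_count, r.total_count) == (0, 2)
        assert r.ratio == 0.0

    def test_all_unique(self):
        m = make_matrix(
            {"s1": {"A": True, "B": False}, "s2": {"A": False, "B": True}},
            {"s1": "case", "s2": "case"},
        )
        assert ut_ratio(m, "case").ratio == 1.0

    def test_small_fixture(self, small_matrix):
        r = ut_ratio(small_matrix, "case")
        # B, C, E appear once among cases; D never; A three times
        assert (r.unique_count, r.total_count) == (3, 4)

    def test_matches_brute_force_recount(self, rng):
        presence = rng.random((5, 20)) < 0.4
        df = pd.DataFrame(
            presence, index=[f"s{i}" for i in range(5)],
            columns=[f"sp{j}" for j in range(20)],
        )
        m = DetectionMatrix(
            modality="culturomics", presence=df,
            groups=pd.Series({f"s{i}": "case" for i in range(5)}),
        )
        r = ut_ratio(m, "case")
        colsum = presence.sum(axis=0)
        assert r.unique_count == int((colsum == 1).sum())
        assert r.total_count == int((colsum >= 1).sum())

    def test_published_rendering(self):
        assert str(UTResult(151, 335)) == "151/335 (45%)"
        assert str(UTResult(185, 281)) == "185/281 (66%)"

    def test_zero_total_errors(self, small_matrix):
        with pytest.raises(ValidationError):
            ut_ratio(small_matrix, "case", species_subset=["Z"])

    def test_sample_and_species_order_invariance(self, small_matrix, rng):
        r = ut_ratio(small_matrix, "case")
        perm = small_matrix.presence.sample(frac=1, axis=1, random_state=7)
        shuffled = DetectionMatrix(
            modality="culturomics",
            presence=perm.sample(frac=1, axis=0, random_state=3),
            groups=small_matrix.groups,
        )
        r2 = ut_ratio(shuffled, "case")
        assert (r.unique_count, r.total_count) == (r2.unique_count, r2.total_count)

    def test_duplicating_a_sample_never_increases_unique(self, small_matrix):
        before = ut_ratio(small_matrix, "case").unique_count
        dup = small_matrix.presence.loc[["k1"]].rename(index={"k1": "k1b"})
        presence = pd.concat([small_matrix.presence, dup])
        groups = pd.concat([small_matrix.groups, pd.Series({"k1b": "case"})])
        bigger = DetectionMatrix(modality="culturomics", presence=presence, groups=groups)
        assert ut_ratio(bigger, "case").unique_count <= before


class TestShannon:
    def test_single_species_zero(self):
        assert shannon_index({"A": 10}).h_bits == 0.0

    def test_uniform_four_species_two_bits(self):
        assert shannon_index([1, 1, 1, 1]).h_bits == pytest.approx(2.0)

    def test_matches_term_by_term_oracle(self, rng):
        counts = rng.integers(1, 1000, size=10).astype(float)
        p = counts / counts.sum()
        expected = -sum(pi * np.log2(pi) for pi in p)
        assert shannon_index(counts).h_bits == pytest.approx(expected, abs=1e-12)

    def test_zero_entries_ignored(self):
        assert shannon_index([2, 2, 0, 0]).h_bits == pytest.approx(1.0)

    def test_all_zero_after_filter_errors(self):
        with pytest.raises(ValueError):
            shannon_index({"A": 1.0}, scope_filter=lambda name: name != "A")

    def test_scope_renormalizes(self):
        # within the {A, B} subset the composition is uniform
        r = shannon_index({"A": 10, "B": 10, "C": 80}, scope_filter=lambda n: n != "C")
        assert r.h_bits == pytest.approx(1.0)
        assert r.n_species == 2

    def test_global_proportion_mode_is_contribution_only(self):
        r = shannon_index(
            {"A": 10, "B": 10, "C": 80},
            scope_filter=lambda n: n != "C",
            renormalize=False,
        )
        expected = -2 * 0.1 * np.log2(0.1)
        assert r.h_bits == pytest.approx(expected)
        assert not r.proper

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=12))
    def test_permutation_invariant_and_merge_decreases(self, counts):
        base = shannon_index(counts).h_bits
        perm = shannon_index(list(reversed(counts))).h_bits
        assert base == pytest.approx(perm, abs=1e-9)
        merged = [counts[0] + counts[1], *counts[2:]]
        assert shannon_index(merged).h_bits <= base + 1e-9


class TestUnknownDiversity:
    def test_new_taxa_control_has_26_new_taxa(self):
        df = load_new_taxa()
        catalog = load_new_taxa_catalog()
        control_species = df.loc[df["origin"] == "control", "species"]
        counts = unknown_diversity(control_species, catalog, "culturomics")
        assert counts.n_new_species == 26

    def test_new_taxa_case_has_18_new_taxa(self):
        df = load_new_taxa()
        catalog = load_new_taxa_catalog()
        case_species = df.loc[df["origin"] == "case", "species"]
        counts = unknown_diversity(case_species, catalog, "culturomics")
        assert counts.n_new_species == 18

    def test_empty_sample_all_zero(self):
        counts = unknown_diversity([], load_new_taxa_catalog(), "culturomics")
        assert counts.culturomics_total == 0

    def test_metagenomics_passthrough(self):
        counts = unknown_diversity(None, None, "metagenomics", n_unidentified_otus=7)
        assert counts.n_unidentified_otus == 7

    def test_modality_input_mismatch_errors(self):
        with pytest.raises(ValidationError):
            unknown_diversity(["A"], load_new_taxa_catalog(), "metagenomics",
                              n_unidentified_otus=3)
        with pytest.raises(ValidationError):
            unknown_diversity(None, None, "culturomics")

    def test_unresolvable_species_raises_or_warns(self):
        catalog = load_new_taxa_catalog()
        with pytest.raises(ValidationError):
            unknown_diversity(["Not a species"], catalog, "culturomics")
        with pytest.warns(UserWarning):
            counts = unknown_diversity(
                ["Not a species"], catalog, "culturomics", on_missing="warn"
            )
        assert counts.culturomics_total == 0


class TestTaxonFrequency:
    def test_repertoire_phylum_counts(self):
        catalog = load_missing_repertoire_catalog()
        table = taxon_frequency_table(catalog.names(), catalog, "phylum")
        by_taxon = table.set_index("taxon")["count"]
        assert by_taxon["Firmicutes"] == 32
        assert by_taxon["Actinobacteria"] == 5
        assert table["proportion"].sum() == pytest.approx(1.0)

    def test_single_species(self):
        catalog = SpeciesCatalog([SpeciesRecord(name="Alpha primus", phylum="Firmicutes")])
        table = taxon_frequency_table(["Alpha primus"], catalog, "phylum")
        assert table.loc[0, "proportion"] == 1.0

    def test_matches_groupby_oracle(self, rng):
        catalog = load_missing_repertoire_catalog()
        names = list(catalog.names())
        subset = [names[i] for i in rng.choice(len(names), size=20, replace=False)]
        table = taxon_frequency_table(subset, catalog, "genus").set_index("taxon")
        counted: dict[str, int] = {}
        for name in subset:
            counted[catalog[name].genus] = counted.get(catalog[name].genus, 0) + 1
        assert table["count"].to_dict() == counted

    def test_invalid_rank(self):
        with pytest.raises(ValueError):
            taxon_frequency_table([], load_missing_repertoire_catalog(), "kingdom")
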