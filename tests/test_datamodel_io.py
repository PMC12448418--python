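"""Community table containers, TSV round-trips, and structural filters."""

import numpy as np
import pandas as pd
import pytest

from hostgen.datamodel import (
    CommunityTable,
    CommunityTableError,
    filter_host_families,
    phylum_members,
    to_presence_absence,
)
from hostgen.io import read_community_table, write_community_table


def test_roundtrip_identity(make_table, tmp_path):
    table = make_table([[0, 3, 1, 5], [2, 0, 0, 4], [1, 1, 0, 0]])
    write_community_table(table, tmp_path / "c.tsv", tmp_path / "m.tsv")
    back = read_community_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
    assert back.counts.to_numpy().tolist() == table.counts.to_numpy().tolist()
    assert list(back.host_ids) == list(table.host_ids)
    assert back.metadata.equals(table.metadata)


def test_missing_host_in_metadata_names_the_host(tmp_path):
    pd.DataFrame([[1, 2], [3, 4]], index=["h1", "h2"], columns=["a1", "a2"]).to_csv(
        tmp_path / "c.tsv", sep="\t"
    )
    pd.DataFrame(
        {"site": ["s"], "host_species": ["x"], "host_family": ["f"]}, index=["h1"]
    ).to_csv(tmp_path / "m.tsv", sep="\t")
    with pytest.raises(CommunityTableError, match="h2"):
        read_community_table(tmp_path / "c.tsv", tmp_path / "m.tsv")


def test_non_integer_counts_rejected(tmp_path, make_table):
    pd.DataFrame([[1.5, 2]], index=["h1"], columns=["a1", "a2"]).to_csv(
        tmp_path / "c.tsv", sep="\t"
    )
    pd.DataFrame(
        {"site": ["s"], "host_species": ["x"], "host_family": ["f"]}, index=["h1"]
    ).to_csv(tmp_path / "m.tsv", sep="\t")
    with pytest.raises(CommunityTableError):
        read_community_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
    with pytest.raises(CommunityTableError):
        make_table([[-1, 2]])


def test_zero_columns_retained(make_table, tmp_path):
    """Singleton and absent ASV columns survive IO (singletons are kept)."""
    table = make_table([[0, 3], [0, 1]])
    write_community_table(table, tmp_path / "c.tsv", tmp_path / "m.tsv")
    back = read_community_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
    assert back.n_asvs == 2
    assert back.prevalence().tolist() == [0, 2]


class TestFamilyFilter:
    def test_family_at_seven_hosts_removed(self, make_table):
        counts = np.ones((10, 2), dtype=int)
        table = make_table(counts, families=["small"] * 7 + ["big"] * 3, sites=["s"] * 10)
        # default threshold needs >= 8 per family: "small" (7 hosts) goes
        out = filter_host_families(make_table(np.ones((15, 2), dtype=int),
                                              families=["small"] * 7 + ["big"] * 8,
                                              sites=["s"] * 15))
        assert set(out.host_family) == {"big"}
        assert out.n_hosts == 8

    def test_identity_when_all_families_large(self, make_table):
        table = make_table(np.ones((4, 2), dtype=int), families=["f"] * 4)
        out = filter_host_families(table, min_samples=2)
        assert out.equals(table)

    def test_retained_count_matches_brute_force(self, make_table):
        rng = np.random.default_rng(3)
        fams = list(rng.choice(["f1", "f2", "f3", "f4"], size=40))
        table = make_table(rng.integers(0, 5, (40, 6)), families=fams)
        out = filter_host_families(table, min_samples=9)
        expected = sum(c for c in pd.Series(fams).value_counts() if c >= 9)
        assert out.n_hosts == expected

    def test_empty_result_is_an_error(self, make_table):
        table = make_table(np.ones((3, 2), dtype=int), families=["a", "b", "c"])
        with pytest.raises(CommunityTableError):
            filter_host_families(table, min_samples=2)


class TestPresenceAbsence:
    def test_binarization_and_metadata(self, make_table):
        table = make_table([[0, 3, 1]])
        out = to_presence_absence(table)
        assert out.counts.to_numpy().tolist() == [[0, 1, 1]]
        assert out.metadata.equals(table.metadata)

    def test_idempotent_on_binary(self, make_table):
        table = make_table([[0, 1], [1, 1]])
        assert to_presence_absence(table).equals(table)

    def test_column_sums_equal_prevalence(self, make_table):
        rng = np.random.default_rng(0)
        table = make_table(rng.integers(0, 4, (12, 9)))
        pa = to_presence_absence(table)
        manual = [(table.counts[c] > 0).sum() for c in table.counts.columns]
        assert pa.counts.sum(axis=0).tolist() == manual
        assert table.prevalence().tolist() == manual

    def test_commutes_with_family_filter(self, make_table):
        rng = np.random.default_rng(1)
        fams = ["f1"] * 5 + ["f2"] * 3
        table = make_table(rng.integers(0, 3, (8, 5)), families=fams)
        a = to_presence_absence(filter_host_families(table, 4))
        b = filter_host_families(to_presence_absence(table), 4)
        assert a.equals(b)

    def test_prevalence_invariant_under_host_reordering(self, make_table):
        rng = np.random.default_rng(2)
        table = make_table(rng.integers(0, 3, (10, 7)))
        shuffled = table.subset_hosts(list(rng.permutation(table.host_ids)))
        assert shuffled.prevalence().equals(table.prevalence())


class TestPhylumMembers:
    def test_basic_membership(self, small_taxonomy):
        assert phylum_members(small_taxonomy, "Proteobacteria") == {"a1", "a2", "a3"}

    def test_synonym_map_folds_class_level_labels(self, small_taxonomy):
        # a5 is recorded under the class Clostridia, formerly in Firmicutes
        members = phylum_members(
            small_taxonomy, "Firmicutes", synonyms={"Clostridia": "Firmicutes"}
        )
        assert members == {"a4", "a5"}

    def test_unknown_label_warns_and_returns_empty(self, small_taxonomy):
        with pytest.warns(UserWarning, match="not present"):
            assert phylum_members(small_taxonomy, "Cyanobacteria") == set()

    def test_total_synonym_map_partitions_asvs(self, small_taxonomy):
        synonyms = {"Clostridia": "Firmicutes"}
        labels = {"Proteobacteria", "Firmicutes"}
        sets = [phylum_members(small_taxonomy, l, synonyms) for l in labels]
        union = set().union(*sets)
        assert union == set(small_taxonomy.asv_ids)
        assert sum(len(s) for s in sets) == len(union)
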