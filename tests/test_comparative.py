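"""Comparative layer: tables, proportions, presence/absence, clustering."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from algatf import comparative as cp
from algatf.records import Assignment


@pytest.fixture(scope="module")
def table():
    return cp.algal_counts()


@pytest.fixture(scope="module")
def pub_totals():
    return cp.algal_totals()


class TestCountTable:
    def test_counts_from_assignments(self, ruleset):
        assignments = {
            "sp1": [
                Assignment("a", "bZIP"),
                Assignment("b", "bZIP"),
                Assignment("c", "HSF"),
                Assignment("d", "unclassified"),
            ]
        }
        t = cp.count_table(assignments, ruleset)
        assert t.loc["sp1", "bZIP"] == 2
        assert t.loc["sp1", "HSF"] == 1
        assert cp.totals(t)["sp1"] == 3

    def test_unknown_family_is_an_error(self, ruleset):
        with pytest.raises(ValueError, match="NotAFamily"):
            cp.count_table({"sp1": [Assignment("a", "NotAFamily")]}, ruleset)

    def test_zero_assignments_gives_zero_table(self, ruleset):
        t = cp.count_table({"sp1": []}, ruleset)
        assert t.to_numpy().sum() == 0

    def test_published_species_totals(self, table):
        tot = cp.totals(table)
        assert tot["P. tricornutum"] == 196
        assert tot["T. lutea"] == 155
        assert tot["Pavlova sp."] == 128
        assert tot["E. huxleyi"] == 478


class TestProportions:
    def test_reference_percentages(self, table, pub_totals):
        props = cp.display_proportions(table, species_totals=pub_totals)
        assert props.loc["T. lutea", "Fungal TRF"] == 9.03
        assert props.loc["P. tricornutum", "HSF"] == 34.18
        assert props.loc["P. tricornutum", "bZIP"] == 12.76
        assert props.loc["P. purpureum", "C2H2"] == 30.15
        assert props.loc["E. huxleyi", "AP2"] == 12.13

    def test_zero_count_gives_zero_percent(self, table):
        assert cp.proportions(table).loc["T. lutea", "WRKY"] == 0.0

    def test_columns_sum_to_100(self, table):
        sums = cp.proportions(table).sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_zero_total_is_an_error_naming_species(self, ruleset):
        t = cp.count_table({"empty_sp": []}, ruleset)
        with pytest.raises(ValueError, match="empty_sp"):
            cp.proportions(t)


class TestCombinedPercentage:
    def test_ap2_erf_combined(self, table):
        v = cp.combined_percentage(table, "E. huxleyi", ["AP2", "ERF"])
        assert v == pytest.approx(100 * (58 + 99) / 478)
        assert round(v) == 33

    def test_all_families_is_100(self, table):
        assert cp.combined_percentage(
            table, "T. lutea", list(table.columns)
        ) == pytest.approx(100.0)

    def test_singleton_group_equals_proportion(self, table):
        v = cp.combined_percentage(table, "T. lutea", ["HSF"])
        assert v == pytest.approx(cp.proportions(table).loc["T. lutea", "HSF"])

    def test_partition_sums_to_100(self, table):
        cols = list(table.columns)
        parts = [cols[:10], cols[10:25], cols[25:]]
        total = sum(cp.combined_percentage(table, "E. huxleyi", p) for p in parts)
        assert total == pytest.approx(100.0)

    def test_empty_group_is_an_error(self, table):
        with pytest.raises(ValueError):
            cp.combined_percentage(table, "T. lutea", [])


class TestShaqkyfRatio:
    @pytest.mark.parametrize(
        "species,expected",
        [
            ("P. tricornutum", 50.0),
            ("N. gaditana", 53.3),
            ("P. purpureum", 69.6),
        ],
    )
    def test_union_denominator_values(self, table, species, expected):
        assert round(cp.shaqkyf_ratio(table, species), 1) == expected

    def test_zero_shaqkyf_gives_zero(self, ruleset):
        t = pd.DataFrame({"MYB-SHAQKYF": [0], "MYB-rel": [5]}, index=["sp"])
        assert cp.shaqkyf_ratio(t, "sp") == 0.0

    def test_both_zero_is_undefined(self):
        t = pd.DataFrame({"MYB-SHAQKYF": [0], "MYB-rel": [0]}, index=["sp"])
        assert cp.shaqkyf_ratio(t, "sp") is None


class TestPresenceAbsence:
    def test_indicator_of_positive_counts(self):
        t = pd.DataFrame({"A": [0], "B": [3], "C": [1]}, index=["sp"])
        assert list(cp.presence_absence(t).loc["sp"]) == [0, 1, 1]

    def test_family_level_counts_match_published(self, table, ruleset):
        n = cp.n_families(table, ruleset)
        assert n["C. reinhardtii"] == 37
        assert n["T. lutea"] == 27
        assert n["Pavlova sp."] == 24
        assert n["E. huxleyi"] == 25
        assert n["N. gaditana"] == 22

    def test_ap2_erf_rows_collapse_to_one_family_column(self, table, ruleset):
        pres = cp.presence_absence(table, ruleset)
        assert "AP2/ERF" in pres.columns
        assert "AP2" not in pres.columns
        # present when either subfamily is (P. tricornutum has ERF only)
        assert pres.loc["P. tricornutum", "AP2/ERF"] == 1

    def test_invariant_under_assignment_order(self, ruleset):
        a = [Assignment("a", "bZIP"), Assignment("b", "HSF")]
        t1 = cp.count_table({"sp": a}, ruleset)
        t2 = cp.count_table({"sp": list(reversed(a))}, ruleset)
        assert cp.presence_absence(t1).equals(cp.presence_absence(t2))


class TestDendrogram:
    def test_identical_rows_merge_at_height_zero(self):
        pres = pd.DataFrame(
            [[1, 0, 1], [1, 0, 1], [0, 1, 0]], index=["a", "b", "c"]
        )
        tree, _ = cp.dendrogram(pres)
        pair = min(
            (n for n in _iter_nodes(tree) if not n.is_leaf),
            key=lambda n: n.height,
        )
        assert set(pair.leaf_names()) == {"a", "b"}
        assert pair.height == 0.0

    def test_leaf_set_and_newick_parse(self, table, ruleset):
        pres = cp.presence_absence(table, ruleset)
        tree, newick = cp.dendrogram(pres)
        assert sorted(tree.leaf_names()) == sorted(pres.index)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(
            pres.index
        )

    def test_heights_nondecreasing_toward_root(self, table, ruleset):
        tree, _ = cp.dendrogram(cp.presence_absence(table, ruleset))
        for node in _iter_nodes(tree):
            for child in node.children:
                assert child.height <= node.height + 1e-12

    def test_fewer_than_two_species_is_an_error(self):
        with pytest.raises(ValueError):
            cp.dendrogram(pd.DataFrame([[1, 0]], index=["only"]))


def _iter_nodes(tree):
    yield tree
    for c in tree.children:
        yield from _iter_nodes(c)


class TestFamilyClusters:
    def test_k_equal_to_family_count_gives_singletons(self, table):
        props = cp.proportions(table)
        small = props[["HSF", "C2H2", "bZIP"]]
        clusters = cp.family_clusters(small, k=3)
        assert len(set(clusters.values())) == 3

    def test_identical_profiles_cocluster(self):
        props = pd.DataFrame(
            {"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [30.0, 5.0], "D": [0.5, 28.0]},
            index=["sp1", "sp2"],
        )
        clusters = cp.family_clusters(props, k=3)
        assert clusters["A"] == clusters["B"]

    def test_k_larger_than_family_count_is_an_error(self, table):
        with pytest.raises(ValueError):
            cp.family_clusters(cp.proportions(table), k=100)

    def test_deterministic(self, table):
        props = cp.proportions(table)
        assert cp.family_clusters(props, k=4) == cp.family_clusters(props, k=4)
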