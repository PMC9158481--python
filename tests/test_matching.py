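"""Accession normalization, selection matching, and hierarchy grouping."""

import numpy as np
import pytest

from taxicicle import (
    MatchingError,
    build_hierarchy,
    find_taxon,
    match_selection,
    normalize_accession,
)
from taxicicle.matching import is_plausible_accession, match_selection_nested_loops
from taxicicle.taxonomy_io import Lineage, TaxonomyTable

from conftest import make_lineage


class TestNormalizeAccession:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("GB GCA 003170075.1", "GCA_003170075.1"),
            ("GCA_003170075.1", "GCA_003170075.1"),
            ("RS_GCF_000000001.1", "GCF_000000001.1"),
            ("GB_GCA_003170075.1", "GCA_003170075.1"),
        ],
    )
    def test_normalization_rules(self, raw, expected):
        assert normalize_accession(raw) == expected

    def test_idempotent(self):
        once = normalize_accession("GB GCA 003170075.1")
        assert normalize_accession(once) == once

    def test_empty_is_an_error(self):
        with pytest.raises(MatchingError):
            normalize_accession("")

    @pytest.mark.parametrize(
        "text,ok",
        [("GCA_003170075.1", True), ("GCF_000000001.2", True), ("speciesA", False)],
    )
    def test_accession_plausibility(self, text, ok):
        assert is_plausible_accession(text) is ok


class TestMatchSelection:
    def test_single_known_accession_matches(self, small_table):
        result = match_selection(["GB_GCA_000000001.1"], small_table)
        assert result.n == 1
        assert result.unmatched == ()
        assert result.matched[0][0] == "GB_GCA_000000001.1"
        assert result.matched[0][1].genus == "G1"

    def test_partial_match_counts(self, small_table):
        selection = ["GB_GCA_000000001.1", "GB_GCA_000000003.1", "GB_GCA_000000099.1"]
        result = match_selection(selection, small_table)
        assert (len(result.matched), len(result.unmatched)) == (2, 1)
        assert result.n == 3
        assert result.m == 3

    def test_fully_absent_selection_signals_domain_mismatch(self, small_table):
        result = match_selection(["GB_GCA_000000098.1"], small_table)
        assert result.is_empty

    def test_empty_selection_violates_precondition(self, small_table):
        with pytest.raises(MatchingError):
            match_selection([], small_table)

    def test_selection_order_is_preserved(self, small_table):
        selection = ["GB_GCA_000000003.1", "GB_GCA_000000001.1"]
        result = match_selection(selection, small_table)
        assert result.matched_accessions() == tuple(selection)

    def test_agrees_with_nested_loop_oracle_on_random_pairs(self, generated_pair):
        """Indexed lookup is observationally identical to the O(n*m) scan."""
        tree, table = generated_pair
        labels = tree.leaf_labels()
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            selection = [labels[int(i)] for i in rng.integers(0, len(labels), size=n)]
            # sprinkle in accessions absent from the table
            selection += [f"GB_GCA_{int(v):09d}.9" for v in rng.integers(0, 99, size=3)]
            assert match_selection(selection, table) == match_selection_nested_loops(
                selection, table
            )


class TestBuildHierarchy:
    def test_single_lineage_is_a_seven_node_chain(self):
        root = build_hierarchy([("GB_GCA_000000001.1", make_lineage())])
        node, count = root, 0
        while True:
            count += 1
            assert node.size == 1
            if not node.children:
                break
            assert len(node.children) == 1
            node = node.children[0]
        assert count == 7
        assert node.depth == 6
        assert node.id == "GB_GCA_000000001.1"

    def test_shared_genus_merges_with_size_two(self):
        pairs = [
            ("GB_GCA_000000001.1", make_lineage(species="G sp000000001")),
            ("GB_GCA_000000002.1", make_lineage(species="G sp000000002")),
        ]
        root = build_hierarchy(pairs)
        genus = find_taxon(root, 5, "G")
        assert genus.size == 2
        assert len(genus.children) == 2
        node = root
        while node.depth < 5:
            assert node.size == 2
            node = node.children[0]

    def test_distinct_phyla_split_below_the_domain(self):
        pairs = [
            ("GB_GCA_000000001.1", make_lineage(phylum="P1")),
            ("GB_GCA_000000002.1", make_lineage(phylum="P2", genus="H", species="H sp000000002")),
        ]
        root = build_hierarchy(pairs)
        assert root.size == 2
        assert [c.name for c in root.children] == ["P1", "P2"]
        assert all(c.size == 1 for c in root.children)

    def test_sizes_conserve_at_every_internal_node(self, methanomicrobia_hierarchy):
        for node in methanomicrobia_hierarchy.walk():
            if node.depth < 6:
                assert node.size == sum(c.size for c in node.children)
            else:
                assert node.size == 1 and not node.children

    def test_depths_increase_by_one(self, methanomicrobia_hierarchy):
        for node in methanomicrobia_hierarchy.walk():
            for child in node.children:
                assert child.depth == node.depth + 1

    def test_duplicated_input_doubles_internal_sizes(self, generated_pair):
        tree, table = generated_pair
        result = match_selection(tree.leaf_labels(), table)
        base = build_hierarchy(result.matched)
        twins = [
            (acc.replace(".1", ".2"), lineage) for acc, lineage in result.matched
        ]
        doubled = build_hierarchy(list(result.matched) + twins)
        for node in base.walk():
            if node.depth == 6:
                continue
            twin = find_taxon(doubled, node.depth, node.name)
            assert twin.size == 2 * node.size

    def test_mixed_domains_are_rejected(self):
        pairs = [
            ("GB_GCA_000000001.1", make_lineage(domain="Archaea")),
            (
                "GB_GCA_000000002.1",
                Lineage("Bacteria", "P", "C", "O", "F", "G", "G sp000000002"),
            ),
        ]
        with pytest.raises(MatchingError, match="domain"):
            build_hierarchy(pairs)

    def test_empty_input_is_rejected(self):
        with pytest.raises(MatchingError):
            build_hierarchy([])

    def test_sibling_order_follows_first_appearance(self, small_table):
        selection = ["GB_GCA_000000003.1", "GB_GCA_000000001.1", "GB_GCA_000000002.1"]
        result = match_selection(selection, small_table)
        root = build_hierarchy(result.matched)
        family = find_taxon(root, 4, "F")
        assert [g.name for g in family.children] == ["G2", "G1"]
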