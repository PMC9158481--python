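"""Shared fixtures: tiny hand-built trees/tables and generated pairs."""

import pytest

from taxicicle import (
    FixtureSpec,
    build_hierarchy,
    generate_fixture,
    generate_use_case_like,
    match_selection,
    parse_lineage,
    parse_newick,
)
from taxicicle.taxonomy_io import TaxonomyTable


def make_lineage(
    domain="Archaea",
    phylum="P",
    clazz="C",
    order="O",
    family="F",
    genus="G",
    species=None,
):
    species = species or f"{genus} sp000000001"
    return parse_lineage(
        f"d__{domain};p__{phylum};c__{clazz};o__{order};f__{family};"
        f"g__{genus};s__{species}"
    )


@pytest.fixture
def small_table():
    """Three archaeal accessions in two genera of one family."""
    entries = {
        "GCA_000000001.1": make_lineage(genus="G1", species="G1 sp000000001"),
        "GCA_000000002.1": make_lineage(genus="G1", species="G1 sp000000002"),
        "GCA_000000003.1": make_lineage(genus="G2", species="G2 sp000000003"),
    }
    return TaxonomyTable("Archaea", entries)


@pytest.fixture
def four_leaf_tree():
    return parse_newick(
        "((GB_GCA_000000001.1:1,GB_GCA_000000002.1:1):1,"
        "(GB_GCA_000000003.1:1,GB_GCA_000000004.1:1):1);"
    )


@pytest.fixture(scope="session")
def generated_pair():
    """A deterministic 100-species fixture pair."""
    return generate_fixture(FixtureSpec(n_species=100, seed=42))


@pytest.fixture(scope="session")
def methanomicrobia_pair():
    return generate_use_case_like("methanomicrobia-like")


@pytest.fixture(scope="session")
def methanomicrobia_hierarchy(methanomicrobia_pair):
    tree, table = methanomicrobia_pair
    result = match_selection(tree.leaf_labels(), table)
    return build_hierarchy(result.matched)
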