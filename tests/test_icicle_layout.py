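"""Icicle partition layout and zoom-to-taxon filtering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxicicle import (
    LayoutError,
    build_hierarchy,
    find_taxon,
    layout_icicle,
    zoom_to_taxon,
)
from taxicicle.icicle_layout import row_heights
from taxicicle.matching import TaxonNode

from conftest import make_lineage


def chain_hierarchy():
    return build_hierarchy([("GB_GCA_000000001.1", make_lineage())])


def hierarchy_with_phylum_sizes(sizes):
    """One domain, one phylum per entry holding `size` species."""
    pairs = []
    i = 0
    for p, size in enumerate(sizes):
        for _ in range(size):
            i += 1
            pairs.append(
                (
                    f"GB_GCA_{i:09d}.1",
                    make_lineage(
                        phylum=f"P{p}",
                        clazz=f"C{p}",
                        order=f"O{p}",
                        family=f"F{p}",
                        genus=f"G{p}",
                        species=f"G{p} sp{i:09d}",
                    ),
                )
            )
    return build_hierarchy(pairs)


class TestLayoutIcicle:
    def test_child_widths_are_size_proportional(self):
        root = hierarchy_with_phylum_sizes([1, 3])
        rects = layout_icicle(root, 400, 600)
        widths = {r.node.name: r.w for r in rects if r.node.depth == 1}
        assert widths["P0"] == pytest.approx(100.0)
        assert widths["P1"] == pytest.approx(300.0)

    def test_single_lineage_chain_spans_full_width(self):
        rects = layout_icicle(chain_hierarchy(), 400, 600)
        assert len(rects) == 7
        assert all(r.w == pytest.approx(400.0) and r.x == 0.0 for r in rects)

    def test_equal_sized_genera_get_equal_widths(self, methanomicrobia_hierarchy):
        rects = layout_icicle(methanomicrobia_hierarchy, 840, 600)
        genus_widths = {r.node.name: r.w for r in rects if r.node.depth == 5}
        sizes = {
            r.node.name: r.node.size for r in rects if r.node.depth == 5
        }
        by_size = {}
        for name, width in genus_widths.items():
            by_size.setdefault(sizes[name], set()).add(round(width, 9))
        for width_set in by_size.values():
            assert len(width_set) == 1

    def test_row_y_depends_only_on_depth(self, methanomicrobia_hierarchy):
        rects = layout_icicle(methanomicrobia_hierarchy, 840, 600)
        for depth in range(7):
            ys = {r.y for r in rects if r.node.depth == depth}
            assert len(ys) <= 1

    def test_species_row_is_minimized_and_reaches_the_bottom(self):
        rects = layout_icicle(chain_hierarchy(), 400, 600)
        upper_h, species_h = row_heights(600)
        species = [r for r in rects if r.node.depth == 6]
        assert species[0].h == pytest.approx(species_h)
        assert species_h < upper_h
        assert species[0].y + species[0].h == pytest.approx(600.0)

    def test_width_conservation_at_every_internal_node(self, methanomicrobia_hierarchy):
        rects = layout_icicle(methanomicrobia_hierarchy, 840, 600)
        widths = {id(r.node): r.w for r in rects}
        for node in methanomicrobia_hierarchy.walk():
            if node.children:
                total = sum(widths[id(c)] for c in node.children)
                assert total == pytest.approx(widths[id(node)], abs=1e-9)

    def test_children_tile_without_gaps_or_overlap(self, methanomicrobia_hierarchy):
        rects = layout_icicle(methanomicrobia_hierarchy, 840, 600)
        geo = {id(r.node): r for r in rects}
        for node in methanomicrobia_hierarchy.walk():
            if not node.children:
                continue
            cursor = geo[id(node)].x
            for child in node.children:
                assert geo[id(child)].x == pytest.approx(cursor, abs=1e-9)
                cursor += geo[id(child)].w
            assert cursor == pytest.approx(geo[id(node)].x + geo[id(node)].w, abs=1e-9)

    def test_species_row_tiles_the_full_panel(self, methanomicrobia_hierarchy):
        rects = layout_icicle(methanomicrobia_hierarchy, 840, 600)
        species_total = sum(r.w for r in rects if r.node.depth == 6)
        assert species_total == pytest.approx(840.0, abs=1e-9)

    def test_non_positive_panel_is_an_error(self):
        with pytest.raises(LayoutError):
            layout_icicle(chain_hierarchy(), 0, 100)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(sizes=st.lists(st.integers(1, 9), min_size=1, max_size=6))
    def test_width_proportionality_property(self, sizes):
        root = hierarchy_with_phylum_sizes(sizes)
        rects = layout_icicle(root, 1000, 600)
        phyla = [r for r in rects if r.node.depth == 1]
        total = sum(sizes)
        for rect, size in zip(phyla, sizes):
            assert rect.w == pytest.approx(1000 * size / total, abs=1e-9)


class TestZoomToTaxon:
    def test_zoom_on_root_is_identity(self, methanomicrobia_hierarchy):
        zoomed = zoom_to_taxon(methanomicrobia_hierarchy, methanomicrobia_hierarchy)
        assert zoomed.node_count() == methanomicrobia_hierarchy.node_count()
        assert zoomed.size == methanomicrobia_hierarchy.size

    def test_zoom_on_species_yields_a_chain_of_sizes_one(self, methanomicrobia_hierarchy):
        species = find_taxon(
            methanomicrobia_hierarchy, 6, "Methanoregula sp003170075"
        )
        zoomed = zoom_to_taxon(methanomicrobia_hierarchy, species)
        node, count = zoomed, 0
        while True:
            count += 1
            assert node.size == 1
            if not node.children:
                break
            assert len(node.children) == 1
            node = node.children[0]
        assert count == 7
        assert node.name == "Methanoregula sp003170075"

    def test_order_zoom_keeps_chain_plus_full_subtree(self):
        from taxicicle import generate_use_case_like, match_selection

        tree, table = generate_use_case_like("hadarchaeota-like")
        result = match_selection(tree.leaf_labels(), table)
        root = build_hierarchy(result.matched)
        order = find_taxon(root, 3, "Hadarchaeales")
        zoomed = zoom_to_taxon(root, order)
        # chain: domain, phylum, class (3 nodes) + the order's full subtree
        assert zoomed.node_count() == 3 + order.node_count()
        assert zoomed.size == order.size == 8
        assert len(find_taxon(zoomed, 3, "Hadarchaeales").children) == 2
        genera = [n for n in zoomed.walk() if n.depth == 5]
        assert len(genera) == 4

    def test_zoom_is_idempotent(self, methanomicrobia_hierarchy):
        genus = find_taxon(methanomicrobia_hierarchy, 5, "Methanoregula")
        once = zoom_to_taxon(methanomicrobia_hierarchy, genus)
        twice = zoom_to_taxon(once, find_taxon(once, 5, "Methanoregula"))
        assert [(n.name, n.depth, n.size) for n in twice.walk()] == [
            (n.name, n.depth, n.size) for n in once.walk()
        ]

    def test_zoom_does_not_mutate_the_input(self, methanomicrobia_hierarchy):
        before = [(n.name, n.size) for n in methanomicrobia_hierarchy.walk()]
        genus = find_taxon(methanomicrobia_hierarchy, 5, "Methanoregula")
        zoom_to_taxon(methanomicrobia_hierarchy, genus)
        after = [(n.name, n.size) for n in methanomicrobia_hierarchy.walk()]
        assert before == after

    def test_unreachable_target_is_an_error(self, methanomicrobia_hierarchy):
        stranger = TaxonNode(name="Nowhere", depth=3, size=1)
        with pytest.raises(LayoutError):
            zoom_to_taxon(methanomicrobia_hierarchy, stranger)

    def test_ancestor_sizes_shrink_to_the_target(self, methanomicrobia_hierarchy):
        family = find_taxon(methanomicrobia_hierarchy, 4, "Methanoregulaceae")
        zoomed = zoom_to_taxon(methanomicrobia_hierarchy, family)
        assert zoomed.size == family.size
        for node in zoomed.walk():
            if node.depth <= 4:
                assert node.size == family.size
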