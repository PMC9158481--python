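"""Space-filling icicle partition of the taxonomic hierarchy.

Each of the seven ranks is a horizontal band; each taxon a rectangle
whose width is proportional to its subtree size, so equal numbers of
selected species yield equal-sized areas.  Children tile their parent's
horizontal extent gap-free in sibling order.  The species band is
compressed to a minimal height, leaving room for the diagonal species
labels below it; the six bands above share the remaining height
equally.

Zooming filters the hierarchy to the ancestor chain from the domain
down to the clicked taxon plus that taxon's full subtree, with sizes
recomputed over the retained species.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import LayoutError
from .matching import TaxonNode

__all__ = ["IcicleRect", "layout_icicle", "zoom_to_taxon", "row_heights"]

N_LEVELS = 7
#: Species-row height: this fraction of the panel height, floored.
SPECIES_ROW_FRACTION = 0.05
SPECIES_ROW_MIN_UNITS = 12.0


@dataclass(frozen=True)
class IcicleRect:
    """One positioned icicle rectangle bound to its hierarchy node."""

    node: TaxonNode
    x: float
    y: float
    w: float
    h: float


def row_heights(
    panel_height: float,
    species_fraction: float = SPECIES_ROW_FRACTION,
    species_floor: float = SPECIES_ROW_MIN_UNITS,
) -> tuple[float, float]:
    """(height of rows 0–5, height of the species row)."""
    species_h = max(species_fraction * panel_height, species_floor)
    if species_h >= panel_height:
        raise LayoutError("panel too short for seven icicle rows")
    return (panel_height - species_h) / (N_LEVELS - 1), species_h


def layout_icicle(
    root: TaxonNode,
    panel_width: float,
    panel_height: float,
    species_fraction: float = SPECIES_ROW_FRACTION,
    species_floor: float = SPECIES_ROW_MIN_UNITS,
) -> list[IcicleRect]:
    """Partition a hierarchy into icicle rectangles.

    The root spans the full panel width in the depth-0 band; each
    node's width is its parent's width times the ratio of their sizes.
    Widths stay exact reals — rounding happens only at SVG
    serialization — so width conservation holds to floating-point
    accuracy.  Rectangles are returned in pre-order.
    """
    if panel_width <= 0 or panel_height <= 0:
        raise LayoutError(
            f"panel dimensions must be positive, got {panel_width}×{panel_height}"
        )
    if root.size <= 0:
        raise LayoutError("hierarchy root has size 0; nothing to lay out")
    upper_h, species_h = row_heights(panel_height, species_fraction, species_floor)

    def band_y(depth: int) -> float:
        return depth * upper_h

    def band_h(depth: int) -> float:
        return species_h if depth == 6 else upper_h

    rects: list[IcicleRect] = []

    def place(node: TaxonNode, x: float, w: float) -> None:
        rects.append(IcicleRect(node, x, band_y(node.depth), w, band_h(node.depth)))
        cursor = x
        for child in node.children:
            child_w = w * (child.size / node.size)
            place(child, cursor, child_w)
            cursor += child_w

    place(root, 0.0, panel_width)
    return rects


def _path_to(root: TaxonNode, target: TaxonNode) -> list[TaxonNode] | None:
    if root is target:
        return [root]
    for child in root.children:
        sub = _path_to(child, target)
        if sub is not None:
            return [root] + sub
    return None


def _copy_subtree(node: TaxonNode) -> TaxonNode:
    return TaxonNode(
        name=node.name,
        depth=node.depth,
        size=node.size,
        id=node.id,
        children=[_copy_subtree(c) for c in node.children],
    )


def zoom_to_taxon(root: TaxonNode, target: TaxonNode) -> TaxonNode:
    """Filter the hierarchy to the domain→target chain plus target's subtree.

    Every ancestor of the target keeps only its on-path child, so the
    result is a single chain from the domain down to the target,
    followed by the target's full (copied) subtree; ancestor sizes are
    recomputed to the target's size.  Zooming on the root returns an
    unfiltered copy; the operation is idempotent.  The input hierarchy
    is never mutated.
    """
    path = _path_to(root, target)
    if path is None:
        raise LayoutError(
            f"zoom target {target.name!r} (depth {target.depth}) "
            "is not reachable from the hierarchy root"
        )
    zoomed_target = _copy_subtree(target)
    result = zoomed_target
    for ancestor in reversed(path[:-1]):
        result = TaxonNode(
            name=ancestor.name,
            depth=ancestor.depth,
            size=zoomed_target.size,
            id=None,
            children=[result],
        )
    return result
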