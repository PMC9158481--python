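"""Rectangular phylogram layout and ROI-to-accession resolution.

Coordinates follow the SVG convention: origin top-left, y increasing
downward.  Leaf x positions are scaled root-to-leaf path lengths (the
branch lengths being estimated evolutionary times), leaves are evenly
spaced vertically in traversal order, and internal nodes sit at the
mean y of their children.  A rectangular region of interest (ROI)
drawn over the panel selects the leaves whose node anchors fall inside
the closed rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import LayoutError
from .tree_io import PhyloNode, PhyloTree

__all__ = ["TreeLayout", "ROI", "layout_phylogram", "select_roi"]

#: Fraction of the panel width the deepest leaf reaches; the remainder
#: is reserved for leaf labels.
DEFAULT_DEPTH_FRACTION = 0.8


@dataclass(frozen=True)
class ROI:
    """Axis-aligned selection rectangle in panel canvas units.

    Corners are normalized on construction so x0 ≤ x1 and y0 ≤ y1;
    callers may pass them in any order (as a mouse drag would).
    """

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        x0, x1 = sorted((float(self.x0), float(self.x1)))
        y0, y1 = sorted((float(self.y0), float(self.y1)))
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "y0", y0)
        object.__setattr__(self, "y1", y1)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass
class TreeLayout:
    """Node positions of a laid-out phylogram.

    ``positions`` maps each :class:`PhyloNode` (by identity) to canvas
    (x, y); ``scale`` is canvas units per branch-length unit.
    """

    tree: PhyloTree
    positions: dict[PhyloNode, tuple[float, float]]
    panel_width: float
    panel_height: float
    scale: float

    def leaf_anchor(self, leaf: PhyloNode) -> tuple[float, float]:
        return self.positions[leaf]


def _path_lengths(root: PhyloNode) -> dict[PhyloNode, float]:
    depths: dict[PhyloNode, float] = {root: 0.0}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            depths[child] = depths[node] + child.branch_length
            stack.append(child)
    return depths


def _topological_depths(root: PhyloNode) -> dict[PhyloNode, float]:
    depths: dict[PhyloNode, float] = {root: 0.0}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            depths[child] = depths[node] + 1.0
            stack.append(child)
    return depths


def layout_phylogram(
    tree: PhyloTree,
    panel_width: float,
    panel_height: float,
    depth_fraction: float = DEFAULT_DEPTH_FRACTION,
) -> TreeLayout:
    """Compute the rectangular phylogram layout for a panel.

    The scale is chosen so the deepest leaf reaches ``depth_fraction``
    (default 0.8) of the panel width.  When every path length is zero
    (a cladogram with no branch lengths) unit topological depths are
    used instead so the tree still spreads horizontally.
    """
    if panel_width <= 0 or panel_height <= 0:
        raise LayoutError(
            f"panel dimensions must be positive, got {panel_width}×{panel_height}"
        )
    if tree.leaf_count < 1:
        raise LayoutError("tree has no leaves")
    depths = _path_lengths(tree.root)
    max_depth = max(depths[leaf] for leaf in tree.leaves())
    if max_depth == 0.0:
        depths = _topological_depths(tree.root)
        max_depth = max(depths[leaf] for leaf in tree.leaves())
    if max_depth == 0.0:  # single-node tree: the leaf IS the root
        depths = {tree.root: 1.0}
        max_depth = 1.0
    scale = depth_fraction * panel_width / max_depth

    positions: dict[PhyloNode, tuple[float, float]] = {}
    leaves = tree.leaves()
    n = len(leaves)
    for i, leaf in enumerate(leaves):
        y = (i + 0.5) / n * panel_height
        positions[leaf] = (depths[leaf] * scale, y)

    def place(node: PhyloNode) -> float:
        if node.is_leaf:
            return positions[node][1]
        child_ys = [place(child) for child in node.children]
        y = sum(child_ys) / len(child_ys)
        positions[node] = (depths[node] * scale, y)
        return y

    place(tree.root)
    return TreeLayout(tree, positions, panel_width, panel_height, scale)


def select_roi(layout: TreeLayout, roi: ROI) -> list[str]:
    """Accessions of leaves whose anchors lie in the closed ROI rectangle.

    Returned in top-to-bottom y order (which equals traversal order
    since leaves are evenly spaced).  An empty result is allowed.
    """
    hits = [
        (layout.positions[leaf][1], leaf.label)
        for leaf in layout.tree.leaves()
        if roi.contains(*layout.positions[leaf])
    ]
    hits.sort(key=lambda pair: pair[0])
    return [label for _, label in hits]  # type: ignore[misc]
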