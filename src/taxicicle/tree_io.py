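"""Newick tree input/output.

Trees arrive as Newick text whose leaf labels are genome assembly
accession numbers (GTDB convention, e.g. ``GB_GCA_003170075.1``).
Parsing is delegated to :mod:`dendropy`; a light pre-scan supplies
character-offset diagnostics for the common syntax faults (unbalanced
parentheses, missing terminator, nested comments) and strips ``[...]``
comment blocks, which GTDB reference trees use for annotations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

from .errors import NewickParseError, TreeValidationError
from .matching import is_plausible_accession, normalize_accession

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "validate_tree_file",
]


@dataclass(eq=False)
class PhyloNode:
    """One node of a rooted phylogeny.

    ``label`` holds the accession for leaves and optional annotation text
    (bootstrap values, taxon strings) for internal nodes.  ``branch_length``
    is the length of the edge above the node, in the tree's evolutionary
    time units; it is 0.0 where the input gave none.  Child order is the
    order of appearance in the Newick text.
    """

    label: str | None = None
    branch_length: float = 0.0
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["PhyloNode"]:
        """Pre-order traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class PhyloTree:
    """A rooted tree with branch lengths and accession-labeled leaves.

    Leaf labels must be non-empty and unique after accession
    normalization; violation is a fatal :class:`TreeValidationError`
    because they serve as matching keys downstream.
    """

    def __init__(self, root: PhyloNode):
        self.root = root
        self._leaves = [n for n in root.walk() if n.is_leaf]
        seen: dict[str, str] = {}
        for leaf in self._leaves:
            if not leaf.label:
                raise TreeValidationError("tree contains a leaf with an empty label")
            key = normalize_accession(leaf.label)
            if key in seen:
                raise TreeValidationError(
                    f"duplicate leaf label after normalization: {leaf.label!r} "
                    f"collides with {seen[key]!r}"
                )
            seen[key] = leaf.label
        for node in root.walk():
            if node.branch_length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.branch_length} at "
                    f"node {node.label!r}"
                )

    @property
    def leaf_count(self) -> int:
        return len(self._leaves)

    def leaves(self) -> list[PhyloNode]:
        """Leaves in pre-order (top-to-bottom display) order."""
        return list(self._leaves)

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self._leaves]  # type: ignore[misc]


def _strip_comments(text: str) -> str:
    """Remove ``[...]`` comment blocks; nested comments are rejected."""
    out: list[str] = []
    depth = 0
    in_quote = False
    for offset, ch in enumerate(text):
        if in_quote:
            out.append(ch)
            if ch == "'":
                in_quote = False
            continue
        if ch == "'" and depth == 0:
            in_quote = True
            out.append(ch)
        elif ch == "[":
            if depth == 1:
                raise NewickParseError("nested '[' comment", offset)
            depth = 1
        elif ch == "]":
            if depth == 0:
                raise NewickParseError("unmatched ']'", offset)
            depth = 0
        elif depth == 0:
            out.append(ch)
    if depth:
        raise NewickParseError("unterminated '[' comment", len(text))
    return "".join(out)


def _prescan(text: str) -> None:
    """Offset-precise checks dendropy does not report: balance and terminator."""
    depth = 0
    in_quote = False
    for offset, ch in enumerate(text):
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if ch == "'":
            in_quote = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset)
    if in_quote:
        raise NewickParseError("unterminated quoted label", len(text))
    if depth > 0:
        raise NewickParseError("unbalanced '(': missing closing parenthesis", len(text))
    if not text.rstrip().endswith(";"):
        raise NewickParseError("missing ';' terminator", len(text))


def _from_dendropy(node: dendropy.Node) -> PhyloNode:
    if node.is_leaf():
        label = node.taxon.label if node.taxon is not None else node.label
    else:
        label = node.label
    length = node.edge.length if node.edge.length is not None else 0.0
    children = [_from_dendropy(c) for c in node.child_nodes()]
    return PhyloNode(label=label, branch_length=float(length), children=children)


def parse_newick(text: str) -> PhyloTree:
    """Parse Newick text into a :class:`PhyloTree`.

    Topology, child order, labels and branch lengths are preserved;
    missing branch lengths default to 0; quoted labels are unquoted;
    internal-node labels (e.g. bootstrap values) are stored but not
    otherwise interpreted.

    Raises :class:`NewickParseError` on malformed input, naming the
    character offset where one is identifiable.
    """
    if not text or not text.strip():
        raise NewickParseError("empty input", 0)
    text = _strip_comments(text)
    _prescan(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several token-level errors
        raise NewickParseError(f"newick parse failure: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    return PhyloTree(root)


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in "()[]':;, \t\n")


def _format_label(label: str | None) -> str:
    if not label:
        return ""
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_node(node: PhyloNode, parts: list[str], *, with_length: bool) -> None:
    if node.children:
        parts.append("(")
        for i, child in enumerate(node.children):
            if i:
                parts.append(",")
            _write_node(child, parts, with_length=True)
        parts.append(")")
    parts.append(_format_label(node.label))
    if with_length:
        parts.append(f":{node.branch_length!r}")


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick text; inverse of :func:`parse_newick`.

    Branch lengths use the shortest decimal representation that
    round-trips, so ``parse_newick(write_newick(t))`` reproduces the
    topology, labels and lengths exactly.
    """
    parts: list[str] = []
    _write_node(tree.root, parts, with_length=False)
    parts.append(";")
    return "".join(parts)


def validate_tree_file(raw: bytes) -> tuple[PhyloTree, list[str]]:
    """Decode, parse, and accession-check an uploaded tree file.

    The file must be UTF-8 text containing a Newick tree whose leaves
    are labeled with assembly accession numbers.  Returns the tree and
    the (possibly empty) list of leaf labels that do not normalize to a
    plausible accession — a warning, not a failure, so that users can
    still view trees labeled with species names.
    """
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise TreeValidationError(f"tree file is not UTF-8 encoded: {exc}") from exc
    tree = parse_newick(text)
    warnings = [
        label
        for label in tree.leaf_labels()
        if not is_plausible_accession(normalize_accession(label))
    ]
    return tree, warnings


def read_tree(path: str) -> PhyloTree:
    """Read a Newick file from disk (UTF-8), ignoring accession warnings."""
    with io.open(path, "rb") as fh:
        tree, _ = validate_tree_file(fh.read())
    return tree
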