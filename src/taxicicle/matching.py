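"""Match selected tree leaves to taxonomy entries and group them.

This is the algorithmic core of the tool: a selection of assembly
accession numbers taken from the phylogenetic tree view is looked up in
the taxonomy table of the chosen domain, and the matched seven-rank
lineages are grouped into a hierarchy whose nodes carry a ``size`` (the
number of selected species in their subtree) and a ``depth`` (rank
index, 0 = domain … 6 = species).  That attributed hierarchy is what
the icicle partition layout consumes.

Semantics follow a straightforward nested scan of the selection against
the domain table — O(n·m) time for n selected species against m table
entries, O(n) space.  The default :func:`match_selection` uses the
table's hash index (O(n)) with observationally identical results;
:func:`match_selection_nested_loops` keeps the literal double loop for
cross-checking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator, Sequence

from .errors import MatchingError

if TYPE_CHECKING:  # avoid an import cycle with taxonomy_io
    from .taxonomy_io import Lineage, TaxonomyTable

__all__ = [
    "MatchResult",
    "TaxonNode",
    "normalize_accession",
    "is_plausible_accession",
    "match_selection",
    "match_selection_nested_loops",
    "build_hierarchy",
    "find_taxon",
]

#: Assembly accessions after normalization: GCA_/GCF_ + 9 digits + version.
_ACCESSION_RE = re.compile(r"^GC[AF]_\d{9}\.\d+$")


def normalize_accession(text: str) -> str:
    """Canonicalize an accession label for use as a matching key.

    Spaces become underscores (UI displays show ``GB GCA 003170075.1``)
    and a leading ``GB_`` (GenBank) or ``RS_`` (RefSeq) database prefix
    is stripped.  The remainder is unchanged and case-sensitive.
    """
    if not text:
        raise MatchingError("cannot normalize an empty accession")
    canonical = text.strip().replace(" ", "_")
    if canonical.startswith(("GB_", "RS_")):
        canonical = canonical[3:]
    return canonical


def is_plausible_accession(normalized: str) -> bool:
    """Whether a normalized label looks like a genome assembly accession."""
    return bool(_ACCESSION_RE.match(normalized))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching a selection against one domain's taxonomy.

    ``matched`` preserves selection order and pairs each original
    (pre-normalization) accession with its lineage; ``n`` is the
    selection length and ``m`` the table size, the two factors of the
    nested-scan cost.
    """

    matched: tuple[tuple[str, "Lineage"], ...]
    unmatched: tuple[str, ...]
    n: int
    m: int

    @property
    def is_empty(self) -> bool:
        """True when nothing matched — the wrong-domain signal."""
        return not self.matched

    def matched_accessions(self) -> tuple[str, ...]:
        return tuple(acc for acc, _ in self.matched)


def _check_selection(accessions: Sequence[str]) -> None:
    if not accessions:
        raise MatchingError("selection is empty; select at least one species")


def match_selection(accessions: Sequence[str], table: "TaxonomyTable") -> MatchResult:
    """Look up each selected accession in the taxonomy table.

    Accessions are normalized before lookup; the result preserves
    selection order.  Unmatched accessions are reported, not fatal — an
    entirely empty match is the caller's cue that the wrong domain was
    chosen.
    """
    _check_selection(accessions)
    matched: list[tuple[str, "Lineage"]] = []
    unmatched: list[str] = []
    for accession in accessions:
        lineage = table.get(normalize_accession(accession))
        if lineage is None:
            unmatched.append(accession)
        else:
            matched.append((accession, lineage))
    return MatchResult(tuple(matched), tuple(unmatched), len(accessions), table.m)


def match_selection_nested_loops(
    accessions: Sequence[str], table: "TaxonomyTable"
) -> MatchResult:
    """Literal O(n·m) double-loop matcher; the semantic reference.

    Scans every table entry for every selected accession.  Kept as an
    independent oracle for :func:`match_selection`.
    """
    _check_selection(accessions)
    items = list(table.entries.items())
    matched: list[tuple[str, "Lineage"]] = []
    unmatched: list[str] = []
    for accession in accessions:
        key = normalize_accession(accession)
        hit = None
        for table_key, lineage in items:
            if table_key == key:
                hit = lineage
                break
        if hit is None:
            unmatched.append(accession)
        else:
            matched.append((accession, hit))
    return MatchResult(tuple(matched), tuple(unmatched), len(accessions), table.m)


@dataclass(eq=False)
class TaxonNode:
    """Node of the grouped, attributed hierarchy.

    ``depth`` is the rank index (0 = domain … 6 = species); ``size`` is
    the number of selected species in the subtree (1 at species level);
    ``id`` is the original accession, present only at species level.
    """

    name: str
    depth: int
    size: int = 0
    id: str | None = None
    children: list["TaxonNode"] = field(default_factory=list)

    def walk(self) -> Iterator["TaxonNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def node_count(self) -> int:
        return sum(1 for _ in self.walk())


def build_hierarchy(lineages: Sequence[tuple[str, "Lineage"]]) -> TaxonNode:
    """Group matched lineages into the size/depth-attributed hierarchy.

    Grouping merges identical (rank, name) pairs under the same parent
    at depths 0–5; species nodes (depth 6) stay one-per-accession with
    size 1 and the accession as ``id``.  Sibling order is first
    appearance in the input, which follows tree leaf order, so the
    icicle's horizontal order mirrors the phylogram's vertical order.
    Internal sizes are the sums of their children's sizes.
    """
    if not lineages:
        raise MatchingError("cannot build a hierarchy from zero matched lineages")
    domains = {lineage.domain for _, lineage in lineages}
    if len(domains) != 1:
        raise MatchingError(
            f"matched lineages span multiple domains: {sorted(domains)}"
        )
    root = TaxonNode(name=domains.pop(), depth=0)
    index: dict[int, dict[str, TaxonNode]] = {id(root): {}}
    for accession, lineage in lineages:
        names = lineage.names()
        parent = root
        for depth in range(1, 6):
            bucket = index[id(parent)]
            child = bucket.get(names[depth])
            if child is None:
                child = TaxonNode(name=names[depth], depth=depth)
                bucket[names[depth]] = child
                parent.children.append(child)
                index[id(child)] = {}
            parent = child
        species = TaxonNode(
            name=names[6], depth=6, size=1, id=accession
        )
        parent.children.append(species)
    _accumulate_sizes(root)
    return root


def _accumulate_sizes(node: TaxonNode) -> int:
    if node.depth == 6:
        return node.size
    node.size = sum(_accumulate_sizes(child) for child in node.children)
    return node.size


def find_taxon(root: TaxonNode, rank_depth: int, name: str) -> TaxonNode:
    """Locate the first node at ``rank_depth`` named ``name`` (pre-order)."""
    for node in root.walk():
        if node.depth == rank_depth and node.name == name:
            return node
    raise MatchingError(f"no taxon named {name!r} at depth {rank_depth}")
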