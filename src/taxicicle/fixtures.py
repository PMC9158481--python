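"""Synthetic, mutually consistent trees and taxonomy tables.

GTDB-scale inputs are large downloads; these generators emulate their
structure at desk scale so every module is exercisable offline.  A
fixture pair consists of a Newick tree whose leaves carry synthetic
``GB_GCA_<9 digits>.1`` accessions and a taxonomy table mapping every
leaf to a full seven-rank lineage of the same domain.  The tree
topology is taxonomy-concordant by construction — species of one genus
form a clade, genera of one family form a clade, and so on — which
makes ROI→icicle expectations computable in closed form.  An optional
leaf-shuffle flag breaks the concordance to test robustness.

Four presets echo real use-case clades (a methanogen class, a
deep-branching archaeal phylum, and two bacterial families) with
synthetic membership and accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TaxicicleError
from .matching import TaxonNode, build_hierarchy, normalize_accession
from .taxonomy_io import Lineage, TaxonomyTable, serialize_lineage
from .tree_io import PhyloNode, PhyloTree, write_newick

__all__ = [
    "FixtureSpec",
    "USE_CASE_PRESETS",
    "generate_fixture",
    "generate_use_case_like",
    "write_fixture_pair",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic fixture.

    Rank counts are per-parent (e.g. ``n_orders_per_class`` orders under
    every class); species are dealt round-robin over the resulting
    genera.  ``branch_length_scale`` is the mean of the exponential
    branch-length draw, in substitutions/site-like units;
    ``max_species_per_genus`` caps genus occupancy (None = unlimited).
    """

    n_species: int = 100
    n_phyla: int = 2
    n_classes_per_phylum: int = 2
    n_orders_per_class: int = 2
    n_families_per_order: int = 2
    n_genera_per_family: int = 2
    branch_length_scale: float = 0.1
    domain_name: str = "Archaea"
    seed: int = 0
    max_species_per_genus: int | None = None
    shuffle_leaves: bool = False

    def n_genera_total(self) -> int:
        return (
            self.n_phyla
            * self.n_classes_per_phylum
            * self.n_orders_per_class
            * self.n_families_per_order
            * self.n_genera_per_family
        )

    def validate(self) -> None:
        counts = (
            self.n_species,
            self.n_phyla,
            self.n_classes_per_phylum,
            self.n_orders_per_class,
            self.n_families_per_order,
            self.n_genera_per_family,
        )
        if any(c < 1 for c in counts):
            raise TaxicicleError(f"all fixture counts must be >= 1, got {counts}")
        if self.branch_length_scale <= 0:
            raise TaxicicleError("branch_length_scale must be positive")
        if (
            self.max_species_per_genus is not None
            and self.n_genera_total() * self.max_species_per_genus < self.n_species
        ):
            raise TaxicicleError(
                f"infeasible spec: {self.n_genera_total()} genera × "
                f"{self.max_species_per_genus} species/genus < {self.n_species}"
            )


def _draw_accessions(rng: np.random.Generator, n: int) -> list[str]:
    """n distinct synthetic GenBank assembly accessions."""
    numbers: set[int] = set()
    while len(numbers) < n:
        numbers.update(int(v) for v in rng.integers(1, 10**9, size=n))
    picked = sorted(numbers)[:n]
    rng.shuffle(picked)  # type: ignore[arg-type]
    return [f"GB_GCA_{num:09d}.1" for num in picked]


def _lineages_from_genus_paths(
    genus_paths: list[tuple[str, str, str, str, str, str]],
    accessions: list[str],
    forced_species: dict[str, str] | None = None,
) -> list[tuple[str, Lineage]]:
    """Deal accessions round-robin over genera; species named '<genus> sp<digits>'."""
    forced_species = forced_species or {}
    pairs: list[tuple[str, Lineage]] = []
    n_genera = len(genus_paths)
    for i, accession in enumerate(accessions):
        domain, phylum, clazz, order, family, genus = genus_paths[i % n_genera]
        digits = normalize_accession(accession).split("_")[1].split(".")[0]
        species = forced_species.get(accession, f"{genus} sp{digits}")
        pairs.append(
            (accession, Lineage(domain, phylum, clazz, order, family, genus, species))
        )
    # keep tree-leaf order grouped by genus (taxonomy-concordant input order)
    pairs.sort(key=lambda p: genus_paths.index(_genus_path_of(p[1])))
    return pairs


def _genus_path_of(lineage: Lineage) -> tuple[str, str, str, str, str, str]:
    return (
        lineage.domain,
        lineage.phylum,
        lineage.clazz,
        lineage.order,
        lineage.family,
        lineage.genus,
    )


def _tree_from_hierarchy(
    root: TaxonNode, rng: np.random.Generator, scale: float
) -> PhyloTree:
    """Mirror the taxonomic hierarchy as a phylogeny with random edge lengths."""

    def convert(node: TaxonNode, is_root: bool) -> PhyloNode:
        length = 0.0 if is_root else float(rng.exponential(scale))
        if node.depth == 6:
            return PhyloNode(label=node.id, branch_length=length)
        children = [convert(c, False) for c in node.children]
        return PhyloNode(label=node.name, branch_length=length, children=children)

    return PhyloTree(convert(root, True))


def _shuffle_leaf_labels(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    leaves = tree.leaves()
    labels = [leaf.label for leaf in leaves]
    order = rng.permutation(len(labels))
    for leaf, idx in zip(leaves, order):
        leaf.label = labels[int(idx)]
    return PhyloTree(tree.root)


def _assemble(
    pairs: list[tuple[str, Lineage]],
    domain_name: str,
    rng: np.random.Generator,
    scale: float,
    shuffle: bool,
) -> tuple[PhyloTree, TaxonomyTable]:
    hierarchy = build_hierarchy(pairs)
    tree = _tree_from_hierarchy(hierarchy, rng, scale)
    if shuffle:
        tree = _shuffle_leaf_labels(tree, rng)
    table = TaxonomyTable(
        domain_name,
        {normalize_accession(acc): lineage for acc, lineage in pairs},
    )
    return tree, table


def generate_fixture(spec: FixtureSpec) -> tuple[PhyloTree, TaxonomyTable]:
    """Generate a (tree, taxonomy table) pair fully determined by the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genus_paths: list[tuple[str, str, str, str, str, str]] = []
    for p in range(spec.n_phyla):
        phylum = f"Phylum-{p + 1:02d}"
        for c in range(spec.n_classes_per_phylum):
            clazz = f"Class-{p + 1:02d}-{c + 1:02d}"
            for o in range(spec.n_orders_per_class):
                order = f"Order-{p + 1:02d}-{c + 1:02d}-{o + 1:02d}"
                for f in range(spec.n_families_per_order):
                    family = f"Family-{p + 1:02d}-{c + 1:02d}-{o + 1:02d}-{f + 1:02d}"
                    for g in range(spec.n_genera_per_family):
                        genus = (
                            f"Genus-{p + 1:02d}-{c + 1:02d}-{o + 1:02d}"
                            f"-{f + 1:02d}-{g + 1:02d}"
                        )
                        genus_paths.append(
                            (spec.domain_name, phylum, clazz, order, family, genus)
                        )
    accessions = _draw_accessions(rng, spec.n_species)
    pairs = _lineages_from_genus_paths(genus_paths, accessions)
    return _assemble(
        pairs, spec.domain_name, rng, spec.branch_length_scale, spec.shuffle_leaves
    )


def _preset_paths(name: str) -> tuple[str, list[tuple[str, ...]], int, int]:
    """(domain, genus paths, n_species, seed) for each use-case preset."""
    if name == "methanomicrobia-like":
        domain, phylum, clazz = "Archaea", "Halobacteriota", "Methanomicrobia"
        layout = {
            "Methanomicrobiales": {
                "Methanoregulaceae": ["Methanoregula", "Methanolinea"],
                "Methanospirillaceae": ["Methanospirillum", "Methanofollis"],
            },
            "Methanosarcinales": {
                "Methanosarcinaceae": ["Methanosarcina", "Methanococcoides"],
                "Methanotrichaceae": ["Methanothrix", "Methanosalsum"],
            },
        }
        n_species, seed = 120, 11
    elif name == "hadarchaeota-like":
        domain, phylum, clazz = "Archaea", "Hadarchaeota", "Hadarchaeia"
        layout = {
            "Hadarchaeales": {
                "Hadarchaeaceae": ["Hadarchaeum", "Hadarchaeum_B"],
                "Hadarchaeaceae_B": ["Hadarchaeum_C", "Hadarchaeum_D"],
            },
        }
        n_species, seed = 8, 13
    elif name == "actinomycetaceae-like":
        domain, phylum, clazz = "Bacteria", "Actinomycetota", "Actinomycetia"
        layout = {
            "Actinomycetales": {
                "Actinomycetaceae": ["Actinomyces", "Schaalia", "Trueperella"],
            },
        }
        n_species, seed = 6, 17
    elif name == "shewanellaceae-like":
        domain, phylum, clazz = "Bacteria", "Pseudomonadota", "Gammaproteobacteria"
        layout = {
            "Enterobacterales": {
                "Shewanellaceae": ["Shewanella"],
            },
        }
        n_species, seed = 8, 19
    else:
        raise TaxicicleError(
            f"unknown use-case preset {name!r}; choose one of {sorted(USE_CASE_PRESETS)}"
        )
    paths = [
        (domain, phylum, clazz, order, family, genus)
        for order, families in layout.items()
        for family, genera in families.items()
        for genus in genera
    ]
    return domain, paths, n_species, seed


USE_CASE_PRESETS = (
    "methanomicrobia-like",
    "hadarchaeota-like",
    "actinomycetaceae-like",
    "shewanellaceae-like",
)

#: The methanogen preset pins one well-known accession so interactive
#: examples (hover, zoom) have a stable target.
_PINNED_ACCESSION = "GB_GCA_003170075.1"
_PINNED_SPECIES = "Methanoregula sp003170075"


def generate_use_case_like(name: str) -> tuple[PhyloTree, TaxonomyTable]:
    """Generate a fixture echoing one of the four use-case clades.

    Rank names follow the clade (synthetic membership and accessions);
    the methanogen preset additionally contains the pinned species
    ``Methanoregula sp003170075`` under accession GB_GCA_003170075.1.
    """
    domain, paths, n_species, seed = _preset_paths(name)
    rng = np.random.default_rng(seed)
    accessions = _draw_accessions(rng, n_species)
    forced: dict[str, str] = {}
    if name == "methanomicrobia-like":
        # pin the known accession into the Methanoregula slot (genus index 0)
        accessions = [a for a in accessions if a != _PINNED_ACCESSION]
        accessions.insert(0, _PINNED_ACCESSION)
        accessions = accessions[:n_species]
        forced[_PINNED_ACCESSION] = _PINNED_SPECIES
    pairs = _lineages_from_genus_paths(list(paths), accessions, forced)  # type: ignore[arg-type]
    return _assemble(pairs, domain, rng, 0.1, shuffle=False)


def write_fixture_pair(
    tree: PhyloTree, table: TaxonomyTable, nwk_path: str, tsv_path: str
) -> None:
    """Write a fixture pair as Newick + GTDB-style taxonomy TSV."""
    with open(nwk_path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")
    with open(tsv_path, "w", encoding="utf-8") as fh:
        for leaf_label in tree.leaf_labels():
            lineage = table.get(normalize_accession(leaf_label))
            if lineage is None:
                raise TaxicicleError(
                    f"fixture closure violated: leaf {leaf_label!r} not in table"
                )
            fh.write(f"{leaf_label}\t{serialize_lineage(lineage)}\n")
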