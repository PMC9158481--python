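# Methods

This note documents the models, conventions, and design choices behind
`taxicicle`, in the package's own words: what the code computes, which
parameters matter, what the synthetic fixtures do and do not emulate,
and where the design was genuinely open.

## Data model

**Tree.** A rooted node-link tree parsed from Newick text.  Branch
lengths are estimated evolutionary times in whatever unit the input
uses; a missing length is read as 0.0 so taxonomy-only cladograms stay
usable.  Leaf labels are genome assembly accessions; internal-node
label strings (bootstrap values, taxon annotations) are preserved but
not displayed.  Bracketed `[...]` comments are stripped before
parsing; nested comments are rejected.  Leaf labels must be unique
*after* accession normalization — they are the matching keys — and a
collision is fatal rather than a warning.  Negative branch lengths are
rejected; inputs carrying the small negative lengths some inference
programs emit should be clamped upstream, a deliberate strictness.

**Lineage.** Exactly seven named ranks in fixed order (domain, phylum,
class, order, family, genus, species), read from GTDB-style
rank-prefixed strings (`d__;p__;c__;o__;f__;g__;s__`).  Placeholder
ranks (nothing after a prefix) are rejected rather than imputed: the
icicle needs seven named layers, and partial lineages have no
well-defined rectangle.  The binomial rule — the species name starts
with its genus name — is enforced at parse time.

**Accession normalization.** Spaces become underscores and one leading
`GB_` (GenBank) or `RS_` (RefSeq) prefix is stripped; the remainder is
case-sensitive.  Display surfaces (tooltips) echo the *original*
label, so a tree labeled `GB GCA 003170075.1` shows exactly that while
matching on `GCA_003170075.1`.

## Matching and grouping

Matching is defined by the nested scan of the selection (length *n*)
against the domain table (size *m*): *O(n·m)* time, *O(n)* space.  The
shipped matcher uses the table's hash index (*O(n)*) and is required —
and tested — to be observationally identical to the literal double
loop, which remains in the code base
(`matching.match_selection_nested_loops`) as the semantic reference.
Unmatched accessions are reported and skipped; only a fully empty
match is escalated, as the wrong-domain signal.

Grouping builds the attributed hierarchy top-down, merging equal
(rank, name) pairs under the same parent at depths 0–5.  Species-level
nodes are never merged: one node per selected accession, size 1,
carrying the accession as its id.  This is the only reading consistent
with both "species nodes have size 1" and the duplication property
(duplicating every lineage under fresh accessions doubles every
internal size).  Sibling order is first appearance in the selection,
which itself follows tree-leaf order, so the icicle's horizontal order
mirrors the phylogram's vertical order — the single source of ordering
truth for both views.

## Layouts

**Phylogram.** SVG conventions: origin top-left, y down, closed
intervals for hit-testing.  Leaf x = scaled root-to-leaf path length,
with the scale chosen so the deepest leaf reaches 80% of the panel
width (the remaining 20% is label space).  Leaves are evenly spaced at
y = (i + ½)/n of the panel height in traversal order; internal nodes
sit at the arithmetic mean of their children's y.  Two degenerate
inputs get explicit treatment: if every path length is zero, unit
topological depths substitute; a single-node tree is pinned at the 80%
depth mark.  ROI selection tests the *leaf node anchor* against the
closed rectangle — label bounding boxes are font-dependent and would
make selection non-deterministic — and returns accessions in
top-to-bottom order.

**Icicle.** The root spans the full panel width in band 0; each child
gets `w·size_child/size_parent` of its parent's extent, tiling
gap-free in sibling order.  Widths are kept as exact reals; rounding
to 3 decimals happens only at SVG serialization, so the conservation
invariants (child widths sum to the parent width; the species band
tiles the panel) hold to 1e-9 in the model.  Row heights: the species
band is `max(0.05 × panel height, 12 canvas units)` — minimized so the
diagonal species labels, drawn below the band, have room — and the six
upper bands share the remainder equally.  The 5%-with-floor rule is a
package choice; only "minimized" is prescribed.

**Zoom.** Zooming onto a taxon filters the hierarchy to the ancestor
chain from the domain down to the target (each ancestor keeping only
its on-path child) plus the target's full subtree, with ancestor sizes
recomputed to the target's size.  A species zoom therefore yields a
pure 7-node chain of sizes 1.  Whether off-path siblings of ancestors
should be retained was an open design point; the pure-chain reading
was adopted because it matches the species-zoom picture and keeps the
operation idempotent.  The zoom never mutates its input, and zoom-out
is a view-state toggle (re-invoking zoom from a zoomed view restores
the full hierarchy) rather than a separate operation.

## Style and rendering

The seven band colors are a clipped sequential blue ramp with white
added for the species layer (`#2171B5`, `#4292C6`, `#6BAED6`,
`#9ECAE1`, `#C6DBEF`, `#EFF3FF`, `#FFFFFF`); the hover highlight is
the complementary orange `#B56521` of the domain blue.  Colors are
configuration with these values as immutable defaults (the ramp is
poor for photocopying, so overrides are allowed); hex codes compare
case-insensitively and serialize uppercase.  Label styling by depth:
species 45° outside the band, family and genus 90° inside, all other
ranks horizontal inside.

The document renderer gives the tree panel 30% of the page width by
default and the icicle the rest, shares one font across panels
(sans-serif, 12 canvas units — unspecified upstream, pinned in tests),
and paints the hovered species' label orange in *both* panels and
nowhere else.  Output is byte-deterministic: fixed element order
(background, icicle rects sorted by (depth, x), tree edges, labels),
3-decimal coordinates, no timestamps or generated ids.  Long labels
are clipped at 30 characters with an ellipsis.  The standalone icicle
export contains exactly one `rect` per hierarchy node, so re-parsing
recovers the node count.  Tooltips are data, not graphics: the
(name, id, size) triple is available programmatically and via the CLI
`inspect` command, with the placement hint "left of the label"
recorded as a constant.

## Synthetic fixtures

The generators emulate the *structure* of reference-database inputs at
desk scale: accessions follow the `GB_GCA_<9 digits>.1` pattern (so
normalization is exercised), every leaf has a full seven-rank lineage,
and the tree mirrors the taxonomic hierarchy — species of a genus form
a clade, and so on up — with branch lengths drawn i.i.d. from an
exponential with mean `branch_length_scale` (default 0.1, a typical
substitutions-per-site scale).  Concordance by construction is what
makes ROI → icicle expectations computable in closed form in tests; an
optional leaf-shuffle flag breaks it to test robustness.  Everything
is determined by the seed.

What the fixtures do **not** emulate: realistic sequence evolution or
rate variation, unbalanced clade sizes and deep rank heterogeneity of
real taxonomies, polyphyly (real trees are not perfectly concordant
with their taxonomy), or database-scale *m* (tens of thousands of
entries).  Passing tests therefore demonstrate correctness of the
matching/grouping/layout machinery, not performance or visual quality
on database-scale inputs.

Four presets echo real clades with synthetic membership: a methanogen
class (120 species across 8 genera, including the pinned species
`Methanoregula sp003170075` under `GB_GCA_003170075.1` as a stable
interactive target), a deep-branching archaeal phylum whose single
order holds 2 families and 4 genera over 8 species, and two bacterial
families (3 genera / 6 species; 1 genus / 8 species sharing one
classification).  The 120-species size of the first preset exists so
selections up to 100 species are drawable from it.

## Sensitivity benchmark

The protocol times icicle production for seeded uniform selections of
20, 40, 60, 80 and 100 species from the methanogen preset, in two
variants: drawing only (partition layout + SVG serialization of a
prebuilt hierarchy) and the full path (matching + grouping + layout +
serialization).  Serialization to an in-memory string is included in
"drawing"; the split can be examined by timing `layout_icicle` and
`icicle_svg_text` separately.  Each record reports mean ± sd over the
repetitions (population sd, so a single run reports 0) on the
monotonic high-resolution clock, and mean time is fitted on selection
size by ordinary least squares, reporting the Pearson correlation.

Two methodological choices matter on shared or
frequency-scaled hardware.  Repetitions are *blocked*: every timed
round visits all (size, variant) scenarios once, so slow drift in
machine speed is shared across scenarios instead of biasing whichever
ran last; and the garbage collector is paused inside the timed loop,
with a few untimed warm-up rounds first.  Without blocking, two
back-to-back runs of the same scenario can differ by a factor of two
while the within-round ordering stays stable.  The default is 100
repetitions per scenario (desk scale; `--runs 1000` reproduces the
full protocol).  Absolute milliseconds are machine properties and are
asserted nowhere; the assertable claims are the linear trend
(correlation ≥ 0.95 in tests), monotone growth with selection size,
and the with-matching variant being slower at every size.

## Known limitations

* One tree + one taxonomy table per invocation; no cross-domain
  documents.
* Internal-node annotations (e.g. bootstrap values) are preserved by
  the parser but not rendered.
* No radial (sunburst) variant, no animated transitions, no rasterized
  output.
* The wrong-domain warning is the only non-fatal failure modeled; I/O
  and format errors are fatal by design.
* Label clipping is character-count based, not glyph-metric based.
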