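# Methods

This note documents the geometry, the resolution and filtering semantics,
the synthetic-data generator, and the numerical and design choices behind
`genarc`.

## Circular layout

Chromosomes are drawn as circumference segments in reference order. With
`n` chromosomes, gap angle `g` degrees (default 1.0°, fixed per
chromosome rather than length-proportional so that small chromosomes stay
visible), and lengths `L_i`:

    span_i = (360 − n·g) · L_i / Σ_j L_j

The first chromosome starts at 12 o'clock and the layout runs clockwise —
a common circular-plot convention; both are configurable
(`start_angle_deg`, `clockwise`). Angles are computed in *sweep*
coordinates (0 at the start, increasing along the drawing direction) so
that the proportionality and conservation identities
(`Σ spans + n·g = 360`, `span_i/span_j = L_i/L_j`) are independent of
direction; conversion to canvas x/y happens only in the renderer.
A genome whose `n·g ≥ 360°` is rejected with a configuration error.

A locus anchors at its midpoint base `m = ⌊(start+end)/2⌋`, mapped to
fraction `(m − ½)/L` of its chromosome's arc. The half-base offset places
each base at its center: base 1 sits half a base-width inside the arc
start, base `L` half a base-width before the arc end, and the map is
strictly increasing and never lands in a gap. Angle placement is exact to
floating point; SVG coordinates are then written with 3 decimals (canvas
units ~1000 wide, so ≈10⁻³ canvas-unit quantization) to keep output bytes
deterministic.

Radially: phenotype glyph ticks sit outermost (default radius 420), the
reference ring (cytobands or composite perimeter colors) spans 382–400,
uploaded annotation rings stack inward in upload order (thickness 18,
spacing 4), and association curves attach at the edge radius (default
250). Configurations whose rings would invade the edge region are
rejected rather than silently squeezed.

## Label resolution

Translation tries, in order: positional syntax `chr:start:end` (1-based
inclusive; `start = end` is a single base; `start < 1` or `start > end`
is malformed), then gene-index lookup. Gene symbols are matched
case-insensitively after trimming; ENSEMBL-shaped (`ENS…` + ≥6 digits)
and all-digit ENTREZ identifiers are matched verbatim, because symbols
vary in case across organisms while identifiers do not. Positional labels
tolerate a `chr` prefix mismatch against the reference's chromosome
naming (`chr12:…` resolves against a chromosome named `12` and vice
versa). Translation never raises: unresolvable labels return an
`Unmapped` marker with a reason that surfaces in the mapping report.

On composite references an explicit `prefix|label` restricts lookup to
one member; un-prefixed labels try members in order and the first hit
wins, with labels that would match several members flagged in the mapping
report. This namespacing dialect is this package's own documented design.

Nodes typed `^PHENO` are treated as coordinate-free by definition, even
when their label would resolve — a phenotype is not a locus. An edge with
one mapped endpoint and one PHENO endpoint is drawn as an outer tick
glyph at the mapped partner's angle; an edge with any other unmapped
endpoint stays in the set (and in grid/text exports) but is excluded from
circular geometry. A set in which *no* edge can be placed at all is a
hard "nothing to plot" error naming the most frequent unmapped labels.

## Filtering, limiting, bundling

Weight filters (`<, <=, >, >=, ==, abs>=, abs<=`) keep edges whose
numeric weight satisfies the predicate; edges without a weight are
dropped by weight filters, since weight filtering is only meaningful
where numeric values were provided. Label-set filters keep edges with at
least one (mode `any`, the default) or both (mode `both`) endpoint labels
in the given set; both endpoint modes are exposed because either reading
is defensible for pathway-style subsetting. Label matching casefolds both
sides — marginally looser than translation's verbatim-identifier rule,
and harmless because ENSEMBL/ENTREZ identifiers are case-stable. Filters
are pure per-edge predicates, hence idempotent and mutually commuting,
and they always run on the full association set.

The render limit (default 2000) truncates only what is drawn — the first
N edges in input order, applied after all filters — never the underlying
set, so `filter ∘ limit` semantics can never degrade into
`limit ∘ filter`.

Bundling partitions each chromosome into consecutive fixed windows of
`window_bp` starting at base 1 (window index `⌊(m−1)/window_bp⌋` for
midpoint `m`). An edge's bundle key is the *unordered* pair of its
endpoint (chromosome, window) cells, so A→B and B→A merge — association
edges are undirected here. Fixed-grid windows were chosen over sliding
neighbourhoods because they give a deterministic, transitive grouping
with a well-defined independent oracle. An optional threshold excludes
edges with `|weight|` at or above it from bundling (absolute value,
matching the magnitude semantics of correlation-style scores); these pass
through for individual drawing. Σ bundle counts + passthrough = number of
participating (mapped–mapped) edges, by construction and by test.

## Rendering

Edges are quadratic Bézier chords: endpoints on the edge-radius circle,
control point on the ray from the center through the chord midpoint at
0.2 × edge radius (a diametric chord's control point is the center).
Stroke color precedence: explicit per-edge color, then the diverging
weight colormap, then neutral grey for unweighted edges. The weight
colormap is a pink–grey–green ramp built so that zero maps to neutral
grey exactly, with domain symmetric in the largest |weight| drawn.
Bundles use stroke width `log₂(count+1)` — a logarithmic law keeps
100-edge bundles readable next to 2-edge ones; the law is this package's
documented choice. Cytoband stains use the conventional Giemsa grey ramp
with red `acen`; node source types use a fixed documented palette.

The SVG contains no timestamps or generated ids, coordinates are written
with fixed precision, and element order is fully determined by input
order, so identical inputs give byte-identical files. A `metadata`
element records the package version and the filter provenance chain.

The bundled human cytoband track is a *coarse synthetic* arm-level
stand-in (p-arm, centromere, q-arm per chromosome, approximate centromere
positions): the full published Giemsa table is deliberately not shipped.
It exercises the stain-rendering path and gives a recognizable outer
ring; users needing true banding can load their own track. Built-in
references ship without genome-scale gene indices — gene tables are
pluggable TSVs (`label chrom start end`), keeping the package free of
large static data and of any runtime network access.

## Synthetic data

The fixture generator emulates the *shape* of real inputs, not their
content: random genomes (default 5 chromosomes of 1–5 Mb), gene indices
in which every gene is reachable by symbol, ENSEMBL-like and ENTREZ-like
alias (so all three label grammars are exercised), association files in
any dialect with correlation-like weights drawn uniform on [−1, 1],
optional explicit colors, and per-edge phenotype endpoints at a
configurable rate. The "correlation study" scenario
(`make_scenario_fig2like`) bundles an 8-chromosome genome (20–80 Mb), 400
genes, weighted edges, two segment-level heatmap rings and two gene-level
bar rings, and a 40-gene pathway-like subset — structurally the inputs of
a copy-number/expression correlation analysis. All generators are driven
by `numpy.random.default_rng(seed)` and are byte-deterministic per seed.

What passing tests on these fixtures does **not** show: real gene
densities, linkage structure, weight distributions of actual analyses, or
real identifier quirks (aliases, versioned ENSEMBL ids, withdrawn
symbols). The generator's uniform weights in particular make weight-
filter thresholds like 0.92 far sparser than in a real correlation
matrix.

Default problem sizes in the test-suite and acceptance script — 100
random genomes for layout properties, 1000-edge sets for filter/bundle
oracles, 1000 random records for round trips, a 2600-edge set for the
render-limit check, one 50 000-edge end-to-end smoke — are the package's
chosen desk-scale regression sizes; all identities they check are
size-independent.

## Known limitations

* A trailing third column that is both a plausible label and a CSS color
  name (`tan`, `plum`) is read as a color; numeric parse is tried first,
  color second, by documented precedence. The ambiguity only exists in
  the optional trailing column, never in label positions.
* Extended SIF allows a weight/color only on single-target lines;
  multi-target lines with a trailing number are not supported (the
  trailing token would be ambiguous with a target name).
* Bar rings use |value| for radial extent; sign is only rendered by the
  histogram style.
* No liftover between genome builds, no sequence storage, no live
  identifier lookups, and no graph analytics (export SIF to a network
  tool for those).
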