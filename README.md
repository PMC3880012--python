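# genarc

Circular genome plots of *omics* association networks, as a headless
Python library and CLI.

Systems-biology analyses — correlation mining, copy-number/expression
integration, protein interaction screens, cross-species phenotype
comparisons — produce ranked association networks whose nodes live on the
genome. `genarc` draws these networks in chromosomal context: chromosomes
become circumference segments whose angular span is proportional to their
base-pair length, nodes are anchored at their genomic positions, and
associations become arcs through the disc. Concentric annotation rings
(bar, histogram, heatmap) display per-gene or per-segment values such as
copy-number gain/loss alongside the network, and features without genomic
coordinates (phenotypes, disease states) appear as tick glyphs outside the
reference ring at their partner's position.

It is aimed at researchers who have association lists as plain text and
want filterable, reproducible, publication-ready SVG figures without a web
stack or a Circos installation.

## The model

* **Layout.** With `n` chromosomes, a per-chromosome gap `g` (default 1°)
  and chromosome lengths `L_i`, chromosome `i` spans
  `(360 − n·g) · L_i / ΣL` degrees, laid out in reference order from
  12 o'clock, clockwise. A locus `chr:start:end` is anchored at its
  midpoint base `m = ⌊(start+end)/2⌋`, at fraction `(m − ½)/L` of its arc.
* **Node labels** mix freely: gene symbols (case-insensitive), ENSEMBL and
  ENTREZ identifiers (verbatim), and positional `chr:start:end` labels
  (1-based, inclusive). Labels may carry an *omics* source-type suffix
  `label^TYPE`, TYPE ∈ {GENO, GEXP, PROT, PHENO}; PHENO marks unmapped
  phenotype features.
* **Edges** optionally carry a numeric weight (p-value, correlation, …)
  *or* an explicit HTML color. Weighted edges are stroked on a diverging
  colormap — green positive, pink negative, neutral grey at zero — scaled
  to the largest |weight| drawn.
* **Filtering** by weight (`<, <=, >, >=, ==, abs>=, abs<=`) and by label
  set (any-endpoint or both-endpoints) always operates on the **full**
  association set; only the render limit (first 2000 edges by default) is
  applied at draw time.
* **Edge bundling** partitions each chromosome into fixed windows of
  `window_bp`; edges whose endpoint midpoints fall in the same unordered
  pair of windows merge into one curve with width `log₂(count+1)`.
  Optionally, edges with `|weight|` above a threshold bypass bundling.
* **References**: ten built-in organism genomes (human, mouse, worm, fly,
  yeast, zebrafish, *Arabidopsis*, rice, tomato, *E. coli*), custom
  organisms from a two-column `chrom<TAB>length_bp` table, and composite
  references that join several organisms on one circle for
  between-organism (e.g. ortholog/phenolog) networks, with
  `prefix|label` namespacing.

Input dialects: space- (`.txt`), tab- (`.tsv`) and comma-delimited
(`.csv`) edge lists `A B [weight-or-color]`, plus Simple Interaction
Format (`.sif`) `A rel B [C D …]` extended with an optional trailing
weight-or-color column. Exports (filtered TSV, SIF for external network
viewers, grid tables, SVG) are valid future inputs where applicable.

## Worked example

Generate a self-contained synthetic scenario (an 8-chromosome genome, a
gene index, 2000 correlation-weighted edges, annotation rings, a 40-gene
pathway-like subset), then plot the high-|correlation| sub-network touching
the subset:

```sh
$ genarc fixtures --seed 1 --n-edges 2000 --out-dir demo
$ genarc plot \
    --organism-custom demo/reference.tsv \
    --gene-index demo/gene_index.tsv \
    --associations demo/associations.tsv \
    --ring demo/ring_0.txt --ring demo/ring_1.txt \
    --weight-op 'abs>=' --weight 0.92 \
    --genes demo/gene_subset.txt \
    --svg demo/plot.svg --tsv demo/filtered.tsv
[genarc] labels: 15 total, 15 mapped, 0 unmapped, 0 phenotype
[genarc] wrote demo/plot.svg
[genarc] wrote demo/filtered.tsv
```

The mapping report describes the *filtered* set: 8 of the 2000 edges
survive `|w| ≥ 0.92` plus subset membership, touching 15 distinct labels,
all of which resolved to loci. `demo/plot.svg` contains the 8 chromosome
bands, the two rings, and the 8 edge curves; `demo/filtered.tsv` starts

```
# labelA	labelB	weight-or-color
G0294	ENSFIX00000000031	-0.955418
G0032	G0198	-0.993802
```

and can be fed straight back via `--associations`. Label translation is
also available on its own:

```sh
$ genarc translate G0001 chr2:100:5000 NOT_A_GENE \
    --organism-custom demo/reference.tsv --gene-index demo/gene_index.tsv
G0001	chr2	44061941	44068521
chr2:100:5000	chr2	100	5000
NOT_A_GENE	unmapped	label not in gene index
```

`genarc references` lists the built-in catalog (10 organisms with builds
and genome sizes); `genarc plot --organism human …` uses them directly,
optionally with your own `--gene-index` table.

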