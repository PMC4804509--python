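# omicsviz

Visualization of integrated multi-omics cancer genomics data in two
layouts: a **matrix layout** (samples as columns, genes as rows) and a
**network-circular layout** (genes as nodes of a co-expression network,
each node carrying concentric per-sample circular tracks).

Translational cancer genomics produces several value types per gene and
sample at once — mRNA and miRNA expression, DNA methylation status, DNA
copy-number variation (CNV) calls — plus clinical sample features.
`omicsviz` is for researchers who need all of these in one figure for a
gene set of interest, without tying the display to genomic coordinates.

## The two layouts

**Matrix layout.** One row per gene, one column per sample. Each cell is
a split heatmap: the top half shows the gene's mRNA log-ratio expression,
the bottom half the expression of the miRNA most negatively correlated
with that gene. The cell outline is colored by methylation status, and a
centered point marks a copy-number gain (+1) or loss (−1); neutral calls
draw nothing. Clinical features appear as colored rectangle rows above
the matrix, and a per-gene summary (e.g. the mean fold change between
tissue groups) is listed at the right as text or signed bars.

**Network-circular layout.** An undirected co-expression network is
inferred from the mRNA matrix: genes *g₁, g₂* are joined iff
|r(g₁, g₂)| ≥ τ (Pearson by default, τ = 0.5); if thresholding leaves the
graph disconnected, edges of a maximum-|r| spanning tree are added so the
displayed network is connected. Nodes are placed by a seeded
force-directed layout with a minimum-spacing guarantee. Each node carries
concentric tracks whose angular sectors are the samples (360°/S each),
inner to outer: tissue groups (polygons), mRNA expression (heatmap),
paired miRNA expression (heatmap), methylation (bars), CNV (points).
Gene labels sit under the nodes.

Both layouts emit a resolution-independent `Scene` of geometric glyphs,
rendered to deterministic SVG or to PNG. Continuous values map onto the
diverging BlueWhiteRed scale clamped to [−3, 3] by default.

## Worked example

```sh
omicsviz generate-data --out demo --seed 1      # 10 genes x 30 samples
omicsviz plot-biomatrix demo/manifest.yaml --out biomatrix.svg
omicsviz plot-bionetcircos demo/manifest.yaml --out bionet.svg --seed 1
```

The matrix plot logs:

```
scene=630x470
glyphs.header=62
glyphs.heatmap=600
glyphs.outline=300
glyphs.cnv=22
glyphs.summary=11
```

600 heatmap rectangles are the split cells (2 × 10 genes × 30 samples),
300 outlines are one methylation frame per cell, and 22 points are
exactly the nonzero CNV calls in the generated data; the 62 header
glyphs are the 2 clinical features × 30 samples plus two row labels, and
the summary column holds one mean-fold-change text per gene plus its
title. The network plot reports 10 node-track groups on a connected
10-node network with its five-entry track legend.

The same calls work from Python:

```python
from omicsviz import SynthParams, generate_dataset, compose_biomatrix
ds = generate_dataset(SynthParams(seed=1))
scene = compose_biomatrix(ds)        # -> Scene of ~1000 glyphs
```

Every layout operation (header, gene row, summary column, node tracks,
sample links, labels) is public, so customized single-gene figures can be
assembled from the parts and combined with `compose_panels`.

## Input format

A dataset directory holds tab-delimited matrices (first row sample ids,
first column gene ids, `NA` for missing), an annotation table (first
column sample id), and a `manifest.yaml` naming each file and its kind
(`continuous` | `category` | `binary`). `omicsviz validate` checks all
container invariants (aligned ids, binary domain {−1, 0, +1}, labeled
category codes).

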