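# Methods

## Data model

A `PlotDataSet` bundles everything one plot needs, aligned on a single
sample order and a single gene order: an ordered list of `OmicsMatrix`
objects (each a gene × sample grid with a declared kind), a
`SampleAnnotation` table of clinical features, optional per-gene
`SummaryData`, and the gene → miRNA pairing map. Kinds fix the value
domain: `continuous` holds real log-ratios (NaN allowed, drawn in a
designated missing-value grey), `category` holds non-negative integer
codes with an attached label table (codes rather than raw strings keep
color binding order-stable), `binary` holds {−1, 0, +1} loss/neutral/gain
calls and forbids missing values. `validate_dataset` reports every
violation (misaligned ids, out-of-domain values, uncovered genes) rather
than stopping at the first.

## miRNA pairing

For each gene the paired miRNA minimizes the correlation coefficient of
its expression with the gene's mRNA across samples. The measure is
Pearson on the values as given; Spearman (rank-transform then Pearson) is
available through the `method` parameter. "Most negatively related" is
interpreted as the most negative coefficient rather than the smallest
one-sided p-value — at a fixed sample count the two orderings coincide,
and the coefficient needs no distributional machinery. Ties break toward
the earlier miRNA row. Zero-variance miRNA rows are skipped with a
warning (their correlation is undefined); a zero-variance gene row is an
error. At least 3 shared samples are required for the coefficient to be
meaningful at all.

## Summary column ("mean fold change")

When generated rather than supplied, the per-gene summary is the mean
over tumor samples minus the mean over normal samples of the already
log-scaled mRNA values, formatted to 2 decimals in text mode. Bar mode
draws signed horizontal bars from a zero baseline, scaled by the largest
absolute value; a zero value degenerates to the baseline tick.

## Matrix layout geometry

All lengths are abstract canvas units (default cell 14 × 20). The left
margin is reserved from the longest gene/feature name at an estimated
0.6 × font-size per character — layouts never measure real fonts; text
glyphs carry only an anchor, string and size, and true metrics belong to
the renderer. CNV point radius is 30% of the cell's smaller dimension
and the methylation outline stroke is 10% of cell height; these are
package constants with no deeper meaning. Row order is the dataset's
gene order — no clustering or dendrogram is applied. Sample names are
drawn rotated 90° under the last gene row (placement is a package
choice). Scenes are validated against an in-bounds invariant: every
glyph's (conservative) bounding box must lie inside the canvas.

## Network construction and placement

The co-expression rule — |Pearson r| ≥ τ with τ = 0.5 by default,
completed to a connected graph with a maximum-|r| spanning tree when
thresholding disconnects it — is this package's construction; τ, the
correlation method, and an explicit edge-list bypass are all exposed.
Node placement runs `networkx.spring_layout` (Fruchterman–Reingold) with
an integer seed, fits positions into the canvas minus a margin that
reserves the full track radius plus the label box, then applies a
deterministic pairwise collision relaxation (up to 300 sweeps, symmetric
push-apart with a 5% overshoot, clamped to the box) until every pair of
node centers is at least `node_spacing` apart (default 2.2 × node
radius, checked with a 1e-6 tolerance). Up to 8 deterministic restarts
(seeds derived from the user seed) are tried before failing with advice
to enlarge the canvas. Any placement satisfying determinism + spacing is
considered conformant; the specific relaxation is an implementation
detail.

## Circular tracks

Angles are degrees in the mathematical convention; sectors start at 12
o'clock and advance clockwise by default (the common circular-genomics
convention), each spanning 360°/S exactly, so the sectors tile the
circle with no overlap for any S. Default radial extents, as fractions
of the node radius: links hole 0–0.20, group polygons 0.20–0.36, mRNA
heatmap 0.36–0.52, miRNA heatmap 0.52–0.68, methylation bars 0.68–0.84,
CNV points 0.84–1.00. Methylation is an outline in the matrix layout but
a bar here; bar length for a category-coded matrix is code / max-code of
the annulus depth (so a 2-level status is either empty or full), and for
a continuous matrix the clamped scale position. Bars are inset 12% of
the sector angle on each side so adjacent samples stay distinguishable.
Neutral CNV draws no point. Sample-link chords are straight segments
between sector mid-angles at the link radius; the package attaches no
semantics to the pairs it is given. Network edges draw beneath node
tracks (a package choice); labels draw on top.

## Colors

BlueWhiteRed is anchored at pure blue → white → pure red with
piecewise-linear 8-bit RGB interpolation; the scale clamps out-of-range
values to its endpoints (standard heatmap practice, consistent with the
legend's bounded min/max of −3/3) and is symmetric about its midpoint:
the positions of v and −v are mirror images. No perceptually-uniform
interpolation is attempted. Categorical palettes assign a tab10-style
cycle in first-appearance order; binary loss/gain default to blue/red
with neutral suppressed.

## Rendering

SVG 1.1 is written with stable element order (layer, then insertion
order), fixed attribute order and all numbers at exactly 3 decimals, so
identical scenes produce byte-identical files — determinism is a
contract, not an accident of the serializer. Arc sectors are true path
arcs in SVG; the PNG rasterizer (Pillow) approximates them with
polygons at ≥ 32 segments per full circle, giving a sagitta error under
0.5% of the radius. Rendering never mutates the scene.

## Synthetic data generator

The generator emulates a two-tissue-group (normal/tumor) cancer cohort:
per-gene baselines N(0, 0.3²); a group shift of ± effect-size (sign
alternating by gene so both directions appear), split symmetrically
about the baseline; Gaussian noise with sd `noise_sd`. Defaults
(effect 2, noise 0.5) keep values predominantly inside the default
[−3, 3] scale bounds, which is why those are the scale's defaults. Each
gene gets exactly one true miRNA with values
−anticorr_strength × mRNA + noise, so at strength 1 and zero noise the
correlation is exactly −1. Methylation is drawn binomially with
P(high) = 0.8 in tumor vs 0.2 in normal; CNV entries are ±1 (fair sign)
with probability `cnv_rate`, else 0. The annotation always carries a
two-level "Tissue Type" feature plus a random "Sex" feature. All draws
flow from one `numpy.random.default_rng(seed)`; no global state.

What this emulates — and does not: real cohorts have correlated gene
modules, batch effects, heavier-tailed expression, many-to-many
miRNA–target relations and CNV segments spanning neighboring genes.
Passing tests therefore demonstrate the layouts' structural correctness
and the estimators' behavior under the stated generative model, not
biological discovery performance on real data.

Default problem sizes are desk-scale (10 genes × 30 samples for the
worked examples; oracle checks on ≤ 10 × 20 toys; recovery over 50
seeds at 60 samples), matching the gene-set-level scope of the layouts.

## Numerical choices and degenerate inputs

Correlations are computed by row-standardized matrix products;
`float_precision="round_trip"` on input parsing makes write → read
round-trips exact. A single-node network goes to the canvas center. One
sample yields a single 360° sector; one gene is legal in the matrix
layout but rejected by network construction (≥ 2 genes, ≥ 3 samples).
Zero-length bars and zero-length summary bars are drawn degenerate
rather than dropped so glyph accounting stays predictable. Out-of-domain
binary values, unknown category codes, unknown ids and overlapping
radial tracks are errors naming the offender.

## Known limitations

No dendrograms or clustering; no gene–gene chords (links are
sample-to-sample within a node); no PDF/EPS backends; no attempt at
pixel-level parity with any other implementation of these layouts; text
extents are estimated, so extreme font substitutions at render time can
crowd (never overflow) reserved label boxes.
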