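"""Matrix layout: samples as columns, genes as rows.

The scene stacks, top to bottom: clinical-feature rectangles (one row per
feature), then one row per gene where each sample cell holds a split
heatmap (top half mRNA, bottom half the gene's paired miRNA), a
methylation-colored cell outline and a copy-number point; gene names sit
at the left, per-gene summary values (text or signed bars) at the right,
sample names rotated under the last row.  Every layout operation is
public so custom single-gene figures can be built from the parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colors import (
    BinaryPalette,
    CategoryPalette,
    ContinuousScale,
    category_palette_for,
    map_binary,
    map_category,
    map_continuous,
)
from .dataset import MatrixKind, PlotDataSet, SampleAnnotation, SummaryData, validate_dataset
from .scene import CHAR_WIDTH_FACTOR, Glyph, Scene

__all__ = [
    "BioMatrixParams",
    "layout_sample_header",
    "layout_gene_row",
    "layout_summary_column",
    "compose_biomatrix",
    "biomatrix_legend",
]


@dataclass
class BioMatrixParams:
    """Geometry and styling knobs for the matrix layout (canvas units)."""

    cell_width: float = 14.0
    cell_height: float = 20.0
    header_row_height: float = 14.0
    gap_between_genes: float = 4.0
    margin: float = 12.0
    font_size: float = 10.0
    summary_mode: str = "text"
    scale: ContinuousScale = field(default_factory=ContinuousScale)
    category_palette: CategoryPalette = field(
        default_factory=lambda: CategoryPalette(
            colors=("#d95f02", "#7570b3"), outline_mode=True,
            labels=("Methyl H", "Methyl L"),
        )
    )
    binary_palette: BinaryPalette = field(default_factory=BinaryPalette)
    heatmap_names: tuple[str, ...] = ("RNASeq", "miRNASeq")
    category_names: tuple[str, ...] = ("Methyl H", "Methyl L")
    binary_names: tuple[str, ...] = ("CN LOSS", "CN Gain")
    point_radius_frac: float = 0.3  # of the cell's smaller dimension
    outline_frac: float = 0.1  # stroke width as fraction of cell height
    summary_bar_width: float = 60.0

    def __post_init__(self) -> None:
        for name in ("cell_width", "cell_height", "header_row_height", "margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.summary_mode not in ("text", "bar"):
            raise ValueError("summary_mode must be 'text' or 'bar'")

    @property
    def char_width(self) -> float:
        return CHAR_WIDTH_FACTOR * self.font_size


def _text_width(s: str, p: BioMatrixParams) -> float:
    return len(s) * p.char_width


def _find_modalities(ds: PlotDataSet):
    """(mRNA, paired miRNA, methylation, CNV) matrices by kind and order."""
    cont = ds.matrices_of_kind(MatrixKind.CONTINUOUS)
    cat = ds.matrices_of_kind(MatrixKind.CATEGORY)
    binm = ds.matrices_of_kind(MatrixKind.BINARY)
    if len(cont) < 2:
        raise ValueError(
            "matrix layout needs two continuous matrices (mRNA + paired miRNA); "
            f"found {len(cont)}"
        )
    if not cat:
        raise ValueError("matrix layout needs a category (methylation) matrix")
    if not binm:
        raise ValueError("matrix layout needs a binary (copy-number) matrix")
    return cont[0], cont[1], cat[0], binm[0]


def _feature_palettes(annotation: SampleAnnotation) -> dict[str, CategoryPalette]:
    return {
        f: category_palette_for(annotation.categories(f))
        for f in annotation.feature_names
    }


def layout_sample_header(
    annotation: SampleAnnotation,
    params: BioMatrixParams,
    origin: tuple[float, float] = (0.0, 0.0),
    palettes: dict[str, CategoryPalette] | None = None,
) -> list[Glyph]:
    """One row of colored rectangles per clinical feature, above the matrix.

    Column k of every row is horizontally aligned with sample k's matrix
    column; colors come from the feature's category palette in
    first-appearance order.
    """
    x0, y0 = origin
    palettes = palettes or _feature_palettes(annotation)
    glyphs: list[Glyph] = []
    for fi, feat in enumerate(annotation.feature_names):
        cats = annotation.categories(feat)
        pal = palettes[feat]
        y = y0 + fi * params.header_row_height
        glyphs.append(Glyph(
            kind="text", coords=(x0 - params.char_width, y + params.header_row_height * 0.75),
            text=feat, anchor="end", font_size=params.font_size,
            color="#000000", layer=2, tag="header:label",
        ))
        for si, lab in enumerate(annotation.labels(feat)):
            glyphs.append(Glyph(
                kind="rect",
                coords=(x0 + si * params.cell_width, y,
                        params.cell_width, params.header_row_height - 2.0),
                color=map_category(cats.index(lab), pal),
                layer=1, tag="header",
            ))
    return glyphs


def layout_gene_row(
    gene: str,
    ds: PlotDataSet,
    row_origin: tuple[float, float],
    params: BioMatrixParams,
) -> list[Glyph]:
    """All glyphs of one gene row.

    Per sample: top-half rect colored by the mRNA value, bottom-half rect
    by the paired miRNA value, a full-cell outline colored by methylation
    category, and a centered point iff the copy-number call is nonzero.
    """
    if gene not in ds.gene_ids:
        raise KeyError(f"gene {gene!r} not in dataset")
    x0, y0 = row_origin
    mrna, mirna, methyl, cnv = _find_modalities(ds)
    gi = ds.gene_ids.index(gene)
    cw, ch = params.cell_width, params.cell_height
    glyphs: list[Glyph] = [Glyph(
        kind="text", coords=(x0 - params.char_width, y0 + ch * 0.65),
        text=gene, anchor="end", font_size=params.font_size,
        color="#000000", layer=2, tag="gene_label",
    )]
    mrna_row = mrna.values[gi]
    mirna_row = mirna.values[gi]
    methyl_row = methyl.values[gi]
    cnv_row = cnv.values[gi]
    half = ch / 2.0
    stroke = params.outline_frac * ch
    r_pt = params.point_radius_frac * min(cw, ch)
    for si in range(len(ds.sample_ids)):
        x = x0 + si * cw
        glyphs.append(Glyph(
            kind="rect", coords=(x, y0, cw, half),
            color=map_continuous(mrna_row[si], params.scale),
            layer=1, tag="heatmap:mrna",
        ))
        glyphs.append(Glyph(
            kind="rect", coords=(x, y0 + half, cw, half),
            color=map_continuous(mirna_row[si], params.scale),
            layer=1, tag="heatmap:mirna",
        ))
        glyphs.append(Glyph(
            kind="rect_outline",
            coords=(x + stroke / 2, y0 + stroke / 2, cw - stroke, ch - stroke),
            color=map_category(int(methyl_row[si]), params.category_palette),
            stroke_width=stroke, layer=3, tag="outline",
        ))
        pt_color = map_binary(int(cnv_row[si]), params.binary_palette)
        if pt_color is not None:
            glyphs.append(Glyph(
                kind="point", coords=(x + cw / 2, y0 + ch / 2, r_pt),
                color=pt_color, layer=4, tag="cnv",
            ))
    return glyphs


def layout_summary_column(
    summary: SummaryData,
    gene_ids: list[str],
    origin: tuple[float, float],
    params: BioMatrixParams,
) -> list[Glyph]:
    """Per-gene summary at the right edge: text values or signed bars.

    ``origin`` is the (x, y) of the column's left edge at the first gene
    row; rows advance by cell_height + gap.  Bars grow right for positive
    values and left for negative ones from a zero baseline at the column
    center; a zero value degenerates to the baseline tick.
    """
    x0, y0 = origin
    for g in gene_ids:
        if g not in summary.per_gene:
            raise KeyError(f"summary {summary.label!r} lacks gene {g!r}")
    glyphs: list[Glyph] = []
    step = params.cell_height + params.gap_between_genes
    if summary.mode == "text":
        values = {g: str(summary.per_gene[g]) for g in gene_ids}
        width = max(_text_width(v, params) for v in values.values())
        for i, g in enumerate(gene_ids):
            glyphs.append(Glyph(
                kind="text",
                coords=(x0 + width, y0 + i * step + params.cell_height * 0.65),
                text=values[g], anchor="end", font_size=params.font_size,
                color="#000000", layer=2, tag="summary",
            ))
    else:
        vals = {g: float(summary.per_gene[g]) for g in gene_ids}
        vmax = max((abs(v) for v in vals.values()), default=0.0) or 1.0
        mid = x0 + params.summary_bar_width / 2.0
        for i, g in enumerate(gene_ids):
            v = vals[g]
            length = abs(v) / vmax * (params.summary_bar_width / 2.0)
            y = y0 + i * step + params.cell_height * 0.25
            h = params.cell_height * 0.5
            x = mid if v >= 0 else mid - length
            glyphs.append(Glyph(
                kind="rect", coords=(x, y, length, h),
                color="#b2182b" if v > 0 else ("#2166ac" if v < 0 else "#000000"),
                layer=2, tag="summary",
            ))
        glyphs.append(Glyph(
            kind="segment",
            coords=(mid, y0, mid, y0 + len(gene_ids) * step - params.gap_between_genes),
            color="#000000", stroke_width=0.8, layer=1, tag="summary:baseline",
        ))
    return glyphs


def _matrix_geometry(ds: PlotDataSet, params: BioMatrixParams):
    """Computed frame: left margin, header origin, matrix origin, width."""
    p = params
    label_pool = list(ds.gene_ids) + ds.annotation.feature_names
    left = p.margin + max(_text_width(s, p) for s in label_pool) + 2 * p.char_width
    n_feat = len(ds.annotation.feature_names)
    top = p.margin
    matrix_top = top + n_feat * p.header_row_height + p.gap_between_genes
    n_s, n_g = len(ds.sample_ids), len(ds.gene_ids)
    matrix_right = left + n_s * p.cell_width
    if ds.summaries:
        s = ds.summaries[0]
        if s.mode == "text":
            sw = max(_text_width(str(s.per_gene[g]), p) for g in ds.gene_ids)
        else:
            sw = p.summary_bar_width
        label_w = _text_width(s.label, p)
        sw = max(sw, label_w)
    else:
        sw = 0.0
    width = matrix_right + (p.char_width * 2 + sw if sw else 0.0) + p.margin
    rows_bottom = matrix_top + n_g * (p.cell_height + p.gap_between_genes)
    sample_label_h = max(_text_width(s, p) for s in ds.sample_ids) + p.char_width
    height = rows_bottom + sample_label_h + p.margin
    return left, top, matrix_top, width, height, rows_bottom


def compose_biomatrix(ds: PlotDataSet, params: BioMatrixParams | None = None) -> Scene:
    """Full matrix-layout scene: header + gene rows + summary + sample names.

    Deterministic: identical inputs give identical scenes.  The dataset
    must pass :func:`validate_dataset` first.
    """
    params = params or BioMatrixParams()
    problems = validate_dataset(ds)
    if problems:
        raise ValueError("invalid dataset: " + "; ".join(problems))
    p = params
    left, top, matrix_top, width, height, rows_bottom = _matrix_geometry(ds, p)
    scene = Scene(width=width, height=height)
    scene.add(*layout_sample_header(ds.annotation, p, origin=(left, top)))
    step = p.cell_height + p.gap_between_genes
    for i, gene in enumerate(ds.gene_ids):
        scene.add(*layout_gene_row(gene, ds, (left, matrix_top + i * step), p))
    if ds.summaries:
        s = ds.summaries[0]
        sx = left + len(ds.sample_ids) * p.cell_width + 2 * p.char_width
        scene.add(Glyph(
            kind="text", coords=(sx, matrix_top - 0.5 * p.gap_between_genes),
            text=s.label, anchor="start", font_size=p.font_size,
            color="#000000", layer=2, tag="summary:title",
        ))
        scene.add(*layout_summary_column(s, ds.gene_ids, (sx, matrix_top), p))
    # sample names under the last gene row, rotated to read downward
    for si, sid in enumerate(ds.sample_ids):
        scene.add(Glyph(
            kind="text",
            coords=(left + (si + 0.35) * p.cell_width, rows_bottom + p.char_width),
            text=sid, anchor="start", font_size=p.font_size, rotation=90.0,
            color="#000000", layer=2, tag="sample_label",
        ))
    return scene


def color_ramp_glyphs(
    scale: ContinuousScale,
    origin: tuple[float, float],
    width: float = 120.0,
    height: float = 12.0,
    n_strips: int = 32,
    font_size: float = 10.0,
) -> list[Glyph]:
    """A horizontal color-ramp bar with vmin/vmax end labels."""
    x0, y0 = origin
    glyphs: list[Glyph] = []
    sw = width / n_strips
    for i in range(n_strips):
        v = scale.vmin + (i + 0.5) / n_strips * (scale.vmax - scale.vmin)
        glyphs.append(Glyph(
            kind="rect", coords=(x0 + i * sw, y0, sw, height),
            color=map_continuous(v, scale), layer=1, tag="legend:ramp",
        ))
    for v, x, anch in ((scale.vmin, x0, "middle"), (scale.vmax, x0 + width, "middle")):
        glyphs.append(Glyph(
            kind="text", coords=(x, y0 + height + font_size),
            text=f"{v:g}", anchor=anch, font_size=font_size,
            color="#000000", layer=2, tag="legend:ramp_label",
        ))
    return glyphs


def biomatrix_legend(
    heatmap_names: tuple[str, ...] = ("RNASeq", "miRNASeq"),
    category_names: tuple[str, ...] = ("Methyl H", "Methyl L"),
    binary_names: tuple[str, ...] = ("CN LOSS", "CN Gain"),
    scale: ContinuousScale | None = None,
    params: BioMatrixParams | None = None,
) -> list[Glyph]:
    """Legend block: color ramp with heatmap names, one outlined swatch per
    category name, one point swatch per binary name, each labeled."""
    params = params or BioMatrixParams()
    scale = scale or params.scale
    p = params
    glyphs: list[Glyph] = []
    x, y = 0.0, 0.0
    glyphs.extend(color_ramp_glyphs(scale, (x, y), font_size=p.font_size))
    glyphs.append(Glyph(
        kind="text", coords=(130.0, y + p.font_size),
        text=" / ".join(heatmap_names), anchor="start", font_size=p.font_size,
        color="#000000", layer=2, tag="legend:heatmap_label",
    ))
    y += 36.0
    sw_w, sw_h = 18.0, 12.0
    for ci, name in enumerate(category_names):
        glyphs.append(Glyph(
            kind="rect_outline", coords=(x, y, sw_w, sw_h),
            color=map_category(ci, p.category_palette),
            stroke_width=2.0, layer=1, tag="legend:category",
        ))
        glyphs.append(Glyph(
            kind="text", coords=(x + sw_w + p.char_width, y + sw_h - 2),
            text=name, anchor="start", font_size=p.font_size,
            color="#000000", layer=2, tag="legend:category_label",
        ))
        y += sw_h + 6.0
    pal = p.binary_palette
    for bi, name in enumerate(binary_names):
        color = pal.color_loss if bi == 0 else pal.color_gain
        glyphs.append(Glyph(
            kind="point", coords=(x + sw_w / 2, y + sw_h / 2, sw_h * 0.35),
            color=color, layer=1, tag="legend:binary",
        ))
        glyphs.append(Glyph(
            kind="text", coords=(x + sw_w + p.char_width, y + sw_h - 2),
            text=name, anchor="start", font_size=p.font_size,
            color="#000000", layer=2, tag="legend:binary_label",
        ))
        y += sw_h + 6.0
    return glyphs
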