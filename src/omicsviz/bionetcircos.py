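"""Circular tracks on a co-expression network.

Genes become nodes of an undirected network inferred from the mRNA matrix
(|correlation| thresholding, completed to a connected graph with a
maximum-|correlation| spanning tree), placed with a seeded force-directed
layout.  Each node carries concentric tracks whose angular sectors are the
samples — by default, inner to outer: sample groups (polygons), mRNA
expression (heatmap), paired-miRNA expression (heatmap), methylation
(bars), copy-number calls (points).  Sample-to-sample chords may be drawn
inside the innermost track; gene labels sit under the nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .biomatrix import color_ramp_glyphs
from .colors import (
    BinaryPalette,
    CategoryPalette,
    ContinuousScale,
    category_palette_for,
    map_binary,
    map_category,
    map_continuous,
)
from .dataset import MatrixKind, OmicsMatrix, PlotDataSet, validate_dataset, _row_correlations
from .scene import CHAR_WIDTH_FACTOR, Glyph, Scene

__all__ = [
    "ExpressionNetwork",
    "TrackSpec",
    "AngularLayout",
    "BioNetParams",
    "build_expression_network",
    "layout_network",
    "layout_node_tracks",
    "layout_sample_links",
    "place_labels",
    "compose_bionetcircos",
    "bionet_legend",
    "default_tracks",
]


@dataclass
class ExpressionNetwork:
    """Undirected gene network; ``positions`` filled in by layout."""

    graph: nx.Graph
    positions: dict[str, tuple[float, float]] | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)


@dataclass(frozen=True)
class TrackSpec:
    """One concentric annulus bound to a data modality and glyph type."""

    data_name: str
    glyph: str  # polygon | heatmap | bar | point | line
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if not 0 < self.r_inner < self.r_outer:
            raise ValueError(
                f"track {self.data_name!r}: need 0 < r_inner < r_outer, "
                f"got [{self.r_inner}, {self.r_outer}]"
            )
        if self.glyph not in ("polygon", "heatmap", "bar", "point", "line"):
            raise ValueError(f"unknown track glyph {self.glyph!r}")


@dataclass(frozen=True)
class AngularLayout:
    """Division of the circle into one sector per sample.

    Angles follow the mathematical convention (degrees counterclockwise
    from 3 o'clock) so the default start of 90 degrees is 12 o'clock;
    the default direction is clockwise, the common circular-genomics
    convention.
    """

    n_sectors: int
    start_angle: float = 90.0
    direction: str = "clockwise"

    def __post_init__(self) -> None:
        if self.n_sectors < 1:
            raise ValueError("need at least one sector")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def sector_width(self) -> float:
        return 360.0 / self.n_sectors

    def sector_bounds(self, k: int) -> tuple[float, float]:
        """(angle_start, angle_end) of sector k, signed along direction."""
        w = self.sector_width
        if self.direction == "clockwise":
            a0 = self.start_angle - k * w
            return (a0, a0 - w)
        a0 = self.start_angle + k * w
        return (a0, a0 + w)

    def mid_angle(self, k: int) -> float:
        a0, a1 = self.sector_bounds(k)
        return (a0 + a1) / 2.0


def _polar(center: tuple[float, float], r: float, angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return (center[0] + r * math.cos(a), center[1] - r * math.sin(a))


# ---------------------------------------------------------------------------
# network construction and placement


def build_expression_network(
    mrna: OmicsMatrix,
    method: str = "pearson",
    threshold: float = 0.5,
) -> ExpressionNetwork:
    """Co-expression network: edge iff |correlation| >= threshold.

    Every gene is a node regardless of edges.  If thresholding leaves the
    graph disconnected, edges of a maximum-|correlation| spanning tree
    are added so the displayed network is connected.  Edge weights store
    the signed correlation.
    """
    genes = mrna.row_ids
    if len(genes) < 2:
        raise ValueError("network needs at least 2 genes")
    if len(mrna.col_ids) < 3:
        raise ValueError("network needs at least 3 samples")
    v = mrna.data.to_numpy(dtype=float)
    for gid, row in zip(genes, v):
        if np.ptp(row) == 0:
            raise ValueError(f"gene {gid!r} has zero variance; correlation undefined")
    r = _row_correlations(v, v, method)
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(r[i, j]) >= threshold:
                g.add_edge(genes[i], genes[j], weight=float(r[i, j]))
    if not nx.is_connected(g):
        full = nx.Graph()
        full.add_nodes_from(genes)
        for i in range(n):
            for j in range(i + 1, n):
                full.add_edge(genes[i], genes[j], absweight=abs(float(r[i, j])))
        mst = nx.maximum_spanning_tree(full, weight="absweight")
        for a, b in mst.edges:
            if not g.has_edge(a, b):
                i, j = genes.index(a), genes.index(b)
                g.add_edge(a, b, weight=float(r[i, j]))
    return ExpressionNetwork(graph=g)


def layout_network(
    net: ExpressionNetwork,
    seed: int,
    canvas: tuple[float, float],
    node_spacing: float,
    margin: float = 0.0,
) -> ExpressionNetwork:
    """Deterministic force-directed placement scaled into the canvas.

    Positions are rescaled so every node center stays ``margin`` inside
    the canvas (reserve the track radius plus label box there) and the
    minimum pairwise center distance is at least ``node_spacing``.  A few
    deterministic layout restarts are tried; if none satisfies the
    spacing the call fails and advises a larger canvas.
    """
    genes = net.nodes
    w, h = canvas
    avail_w, avail_h = w - 2 * margin, h - 2 * margin
    if avail_w <= 0 or avail_h <= 0:
        raise ValueError("canvas smaller than twice the margin; enlarge the canvas")
    if len(genes) == 1:
        return ExpressionNetwork(net.graph, {genes[0]: (w / 2.0, h / 2.0)})
    best: dict[str, tuple[float, float]] | None = None
    best_dist = -1.0
    for attempt in range(8):
        s = (int(seed) + 7919 * attempt) % (2**31 - 1)
        raw = nx.spring_layout(net.graph, seed=s, dim=2)
        pts = np.array([raw[g] for g in genes], dtype=float)
        pts = _fit_to_box(pts, w, h, margin)
        pts = _separate(pts, node_spacing, w, h, margin)
        d = _min_pair_dist(pts)
        if d > best_dist:
            best_dist = d
            best = {g: (float(p[0]), float(p[1])) for g, p in zip(genes, pts)}
        if d >= node_spacing - 1e-6:
            break
    if best_dist < node_spacing - 1e-6:
        raise ValueError(
            f"cannot place {len(genes)} nodes with spacing {node_spacing:g} "
            f"in a {w:g}x{h:g} canvas; enlarge the canvas or shrink the nodes"
        )
    assert best is not None
    return ExpressionNetwork(net.graph, best)


def _min_pair_dist(pts: np.ndarray) -> float:
    n = len(pts)
    return min(
        float(np.hypot(*(pts[i] - pts[j])))
        for i in range(n) for j in range(i + 1, n)
    )


def _fit_to_box(pts: np.ndarray, w: float, h: float, margin: float) -> np.ndarray:
    avail_w, avail_h = w - 2 * margin, h - 2 * margin
    span = pts.max(axis=0) - pts.min(axis=0)
    span[span == 0] = 1.0
    scale = min(avail_w / span[0], avail_h / span[1])
    pts = (pts - pts.min(axis=0)) * scale
    used = (pts.max(axis=0) - pts.min(axis=0))
    pts += [(w - used[0]) / 2.0, (h - used[1]) / 2.0]
    return pts


def _separate(pts: np.ndarray, spacing: float, w: float, h: float,
              margin: float, iterations: int = 300) -> np.ndarray:
    """Deterministic pairwise collision relaxation inside the margin box.

    Nodes closer than ``spacing`` are pushed apart symmetrically along
    their connecting axis, then clamped back into the box; repeats until
    no violation or the iteration budget runs out.
    """
    pts = pts.copy()
    n = len(pts)
    lo = np.array([margin, margin])
    hi = np.array([w - margin, h - margin])
    for _ in range(iterations):
        moved = False
        for i in range(n):
            for j in range(i + 1, n):
                delta = pts[j] - pts[i]
                d = float(np.hypot(*delta))
                if d >= spacing:
                    continue
                if d < 1e-9:
                    # coincident nodes: deterministic axis from the index pair
                    delta = np.array([1.0, 0.5 * ((i + j) % 3 - 1)])
                    d = float(np.hypot(*delta))
                push = (spacing - d) / 2.0 * 1.05
                unit = delta / d
                pts[i] -= unit * push
                pts[j] += unit * push
                moved = True
        np.clip(pts, lo, hi, out=pts)
        if not moved:
            break
    return pts


# ---------------------------------------------------------------------------
# per-node tracks


def default_tracks(node_radius: float) -> list[TrackSpec]:
    """The default five tracks, inner to outer, as radial fractions of the
    node radius (the innermost 20% is left open for sample links)."""
    fr = [
        ("Tissue Type", "polygon", 0.20, 0.36),
        ("RNASeq", "heatmap", 0.36, 0.52),
        ("miRNASeq", "heatmap", 0.52, 0.68),
        ("Methylation", "bar", 0.68, 0.84),
        ("CNV", "point", 0.84, 1.00),
    ]
    return [TrackSpec(n, g, a * node_radius, b * node_radius) for n, g, a, b in fr]


def _track_values(track: TrackSpec, ds: PlotDataSet):
    """Resolve a track's data: annotation feature or matrix row source."""
    if track.data_name in ds.annotation.feature_names:
        return ("feature", track.data_name)
    for m in ds.matrices:
        if m.name == track.data_name:
            return ("matrix", m)
    raise KeyError(
        f"track data {track.data_name!r} is neither an annotation feature nor "
        f"a matrix; have features {ds.annotation.feature_names} and matrices "
        f"{[m.name for m in ds.matrices]}"
    )


def _bar_fraction(m: OmicsMatrix, value: float, scale: ContinuousScale) -> float:
    if m.kind is MatrixKind.CATEGORY:
        mc = m.max_code()
        return (value / mc) if mc else 0.0
    return scale.interp_param(float(value))


def layout_node_tracks(
    gene: str,
    ds: PlotDataSet,
    tracks: list[TrackSpec],
    angular: AngularLayout,
    center: tuple[float, float],
    scale: ContinuousScale | None = None,
    binary_palette: BinaryPalette | None = None,
    feature_palettes: dict[str, CategoryPalette] | None = None,
) -> list[Glyph]:
    """All track glyphs of one node, one angular sector per sample."""
    scale = scale or ContinuousScale()
    binary_palette = binary_palette or BinaryPalette()
    prev_outer = 0.0
    for t in tracks:
        if t.r_inner < prev_outer:
            raise ValueError(
                f"track {t.data_name!r} overlaps the previous track radially"
            )
        prev_outer = t.r_outer
    if gene not in ds.gene_ids:
        raise KeyError(f"gene {gene!r} not in dataset")
    gi = ds.gene_ids.index(gene)
    glyphs: list[Glyph] = []
    n = len(ds.sample_ids)
    if angular.n_sectors != n:
        raise ValueError("angular layout sector count must equal sample count")
    for track in tracks:
        src_kind, src = _track_values(track, ds)
        tag = f"track:{track.glyph}:{track.data_name}"
        if src_kind == "feature":
            if track.glyph != "polygon":
                raise ValueError(
                    f"annotation feature {src!r} can only drive a polygon track"
                )
            cats = ds.annotation.categories(src)
            pal = (feature_palettes or {}).get(src) or category_palette_for(cats)
            labels = ds.annotation.labels(src)
        else:
            row = src.values[gi]
        if track.glyph == "line":
            pts = []
            for k in range(n):
                frac = _bar_fraction(src, float(row[k]), scale)
                r = track.r_inner + frac * (track.r_outer - track.r_inner)
                pts.append(_polar(center, r, angular.mid_angle(k)))
            for a, b in zip(pts[:-1], pts[1:]):
                glyphs.append(Glyph(
                    kind="segment", coords=(a[0], a[1], b[0], b[1]),
                    color="#636363", stroke_width=1.0, layer=3, tag=tag,
                ))
            continue
        for k in range(n):
            a0, a1 = angular.sector_bounds(k)
            if track.glyph == "polygon":
                p_in0 = _polar(center, track.r_inner, a0)
                p_out0 = _polar(center, track.r_outer, a0)
                p_out1 = _polar(center, track.r_outer, a1)
                p_in1 = _polar(center, track.r_inner, a1)
                glyphs.append(Glyph(
                    kind="polygon",
                    coords=(p_in0 + p_out0 + p_out1 + p_in1),
                    color=map_category(cats.index(labels[k]), pal),
                    layer=2, tag=tag,
                ))
            elif track.glyph == "heatmap":
                glyphs.append(Glyph(
                    kind="arc_sector",
                    coords=(center[0], center[1], track.r_inner, track.r_outer, a0, a1),
                    color=map_continuous(float(row[k]), scale),
                    layer=2, tag=tag,
                ))
            elif track.glyph == "bar":
                frac = _bar_fraction(src, float(row[k]), scale)
                pad = 0.12 * (a1 - a0)  # signed: narrows the sector either direction
                glyphs.append(Glyph(
                    kind="arc_sector",
                    coords=(center[0], center[1], track.r_inner,
                            track.r_inner + frac * (track.r_outer - track.r_inner),
                            a0 + pad, a1 - pad),
                    color="#66c2a5", layer=2, tag=tag,
                ))
            elif track.glyph == "point":
                color = map_binary(int(row[k]), binary_palette)
                if color is None:
                    continue
                mid_r = (track.r_inner + track.r_outer) / 2.0
                x, y = _polar(center, mid_r, angular.mid_angle(k))
                glyphs.append(Glyph(
                    kind="point",
                    coords=(x, y, 0.3 * (track.r_outer - track.r_inner)),
                    color=color, layer=3, tag=tag,
                ))
    return glyphs


def layout_sample_links(
    gene: str,
    pairs: list[tuple[str, str]],
    angular: AngularLayout,
    center: tuple[float, float],
    inner_radius: float,
    sample_ids: list[str],
) -> list[Glyph]:
    """Chords between sample sector mid-angles inside the innermost track."""
    glyphs: list[Glyph] = []
    index = {s: i for i, s in enumerate(sample_ids)}
    for a, b in pairs:
        if a not in index:
            raise KeyError(f"unknown sample {a!r} in link pair")
        if b not in index:
            raise KeyError(f"unknown sample {b!r} in link pair")
        if a == b:
            raise ValueError(f"degenerate link from sample {a!r} to itself")
        pa = _polar(center, inner_radius, angular.mid_angle(index[a]))
        pb = _polar(center, inner_radius, angular.mid_angle(index[b]))
        glyphs.append(Glyph(
            kind="segment", coords=(pa[0], pa[1], pb[0], pb[1]),
            color="#969696", stroke_width=0.8, layer=2, tag="link",
        ))
    return glyphs


def place_labels(
    net: ExpressionNetwork,
    label_offset: float = 6.0,
    node_radius: float = 40.0,
    font_size: float = 10.0,
    overrides: dict[str, str] | None = None,
) -> list[Glyph]:
    """One text glyph per gene, centered under its node by default.

    ``overrides`` maps gene -> placement ("above" | "left" | "right") for
    per-node exceptions.
    """
    if net.positions is None:
        raise ValueError("network has no positions; run layout_network first")
    glyphs: list[Glyph] = []
    overrides = overrides or {}
    for gene in net.nodes:
        x, y = net.positions[gene]
        place = overrides.get(gene, "below")
        half_w = CHAR_WIDTH_FACTOR * font_size * len(gene) / 2.0
        if place == "below":
            tx, ty, anch = x, y + node_radius + label_offset + font_size, "middle"
        elif place == "above":
            tx, ty, anch = x, y - node_radius - label_offset, "middle"
        elif place == "left":
            tx, ty, anch = x - node_radius - label_offset, y + font_size / 2, "end"
        elif place == "right":
            tx, ty, anch = x + node_radius + label_offset, y + font_size / 2, "start"
        else:
            raise ValueError(f"unknown label placement {place!r} for {gene!r}")
        glyphs.append(Glyph(
            kind="text", coords=(tx, ty), text=gene, anchor=anch,
            font_size=font_size, color="#000000", layer=5, tag="node_label",
        ))
    return glyphs


# ---------------------------------------------------------------------------
# composer


@dataclass
class BioNetParams:
    """Knobs for the network-circular layout (canvas units)."""

    canvas_width: float = 900.0
    canvas_height: float = 900.0
    node_radius: float = 40.0
    node_spacing: float | None = None  # default 2.2 * node_radius
    seed: int = 0
    method: str = "pearson"
    threshold: float = 0.5
    start_angle: float = 90.0
    direction: str = "clockwise"
    label_offset: float = 6.0
    font_size: float = 10.0
    scale: ContinuousScale = field(default_factory=ContinuousScale)
    binary_palette: BinaryPalette = field(default_factory=BinaryPalette)
    tracks: list[TrackSpec] | None = None
    edges: list[tuple[str, str]] | None = None  # explicit edge list bypasses inference
    links: list[tuple[str, str]] | None = None  # sample-link chords, drawn on every node

    def resolved_tracks(self) -> list[TrackSpec]:
        return self.tracks if self.tracks is not None else default_tracks(self.node_radius)

    @property
    def spacing(self) -> float:
        return self.node_spacing if self.node_spacing is not None else 2.2 * self.node_radius


def compose_bionetcircos(ds: PlotDataSet, params: BioNetParams | None = None) -> Scene:
    """Full network-circular scene: edges under node tracks, labels on top.

    Deterministic for a given seed.  The network is inferred from the
    first continuous matrix (mRNA) unless an explicit edge list is given.
    """
    params = params or BioNetParams()
    p = params
    problems = validate_dataset(ds)
    if problems:
        raise ValueError("invalid dataset: " + "; ".join(problems))
    cont = ds.matrices_of_kind(MatrixKind.CONTINUOUS)
    if not cont:
        raise ValueError("network layout needs a continuous (mRNA) matrix")
    if p.edges is not None:
        g = nx.Graph()
        g.add_nodes_from(ds.gene_ids)
        g.add_edges_from(p.edges)
        net = ExpressionNetwork(graph=g)
    else:
        net = build_expression_network(cont[0], method=p.method, threshold=p.threshold)
    max_label = max(len(g) for g in ds.gene_ids)
    label_w = CHAR_WIDTH_FACTOR * p.font_size * max_label
    margin = p.node_radius + p.label_offset + p.font_size + max(label_w / 2, p.font_size) + 4.0
    net = layout_network(
        net, seed=p.seed, canvas=(p.canvas_width, p.canvas_height),
        node_spacing=p.spacing, margin=margin,
    )
    scene = Scene(width=p.canvas_width, height=p.canvas_height)
    assert net.positions is not None
    for a, b in net.edges:
        xa, ya = net.positions[a]
        xb, yb = net.positions[b]
        scene.add(Glyph(
            kind="segment", coords=(xa, ya, xb, yb),
            color="#cccccc", stroke_width=1.2, layer=0, tag="edge",
        ))
    angular = AngularLayout(
        n_sectors=len(ds.sample_ids),
        start_angle=p.start_angle, direction=p.direction,
    )
    tracks = p.resolved_tracks()
    feat_pals = {
        f: category_palette_for(ds.annotation.categories(f))
        for f in ds.annotation.feature_names
    }
    inner_r = min(t.r_inner for t in tracks)
    for gene in ds.gene_ids:
        center = net.positions[gene]
        scene.add(*layout_node_tracks(
            gene, ds, tracks, angular, center,
            scale=p.scale, binary_palette=p.binary_palette,
            feature_palettes=feat_pals,
        ))
        if p.links:
            scene.add(*layout_sample_links(
                gene, p.links, angular, center, inner_r, ds.sample_ids,
            ))
    scene.add(*place_labels(
        net, label_offset=p.label_offset, node_radius=p.node_radius,
        font_size=p.font_size,
    ))
    return scene


def bionet_legend(
    data_names: tuple[str, ...] = ("Tissue Type", "RNASeq", "miRNASeq", "Methylation", "CNV"),
    scale: ContinuousScale | None = None,
    font_size: float = 10.0,
) -> list[Glyph]:
    """Track-order key (inner to outer) plus the continuous color ramp."""
    if not data_names:
        raise ValueError("data_names must be non-empty")
    scale = scale or ContinuousScale()
    glyphs: list[Glyph] = []
    y = font_size
    glyphs.append(Glyph(
        kind="text", coords=(0.0, y), text="Tracks (inner to outer):",
        anchor="start", font_size=font_size, color="#000000",
        layer=2, tag="legend:key_title",
    ))
    for i, name in enumerate(data_names):
        y += font_size + 4.0
        glyphs.append(Glyph(
            kind="text", coords=(8.0, y), text=f"{i + 1}. {name}",
            anchor="start", font_size=font_size, color="#000000",
            layer=2, tag="legend:key",
        ))
    y += 10.0
    glyphs.extend(color_ramp_glyphs(scale, (8.0, y), font_size=font_size))
    return glyphs
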