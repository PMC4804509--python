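"""Network-circular layout: network inference, placement, tracks, tiling."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import pearsonr

from omicsviz.bionetcircos import (
    AngularLayout,
    BioNetParams,
    ExpressionNetwork,
    TrackSpec,
    build_expression_network,
    compose_bionetcircos,
    bionet_legend,
    default_tracks,
    layout_network,
    layout_node_tracks,
    layout_sample_links,
    place_labels,
)
from omicsviz.dataset import MatrixKind
from omicsviz.render import scene_to_svg

from conftest import make_dataset, make_matrix


class TestBuildNetwork:
    def test_scalar_multiples_give_complete_graph(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = make_matrix("mRNA", MatrixKind.CONTINUOUS,
                        np.vstack([base, 2 * base, -3 * base]))
        net = build_expression_network(m, threshold=0.5)
        assert len(net.edges) == 3  # complete on 3 nodes: |r| = 1 everywhere

    def test_threshold_zero_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        m = make_matrix("mRNA", MatrixKind.CONTINUOUS, rng.normal(size=(5, 10)))
        net = build_expression_network(m, threshold=0.0)
        assert len(net.edges) == 5 * 4 // 2

    def test_matches_brute_force_oracle_with_mst_completion(self):
        rng = np.random.default_rng(3)
        m = make_matrix("mRNA", MatrixKind.CONTINUOUS, rng.normal(size=(6, 20)))
        thr = 0.6
        net = build_expression_network(m, threshold=thr)
        expected = _oracle_edges(m.values, m.row_ids, thr)
        assert {frozenset(e) for e in net.edges} == expected
        assert net.is_connected()

    def test_node_set_is_all_genes_even_without_edges(self):
        rng = np.random.default_rng(1)
        m = make_matrix("mRNA", MatrixKind.CONTINUOUS, rng.normal(size=(4, 30)))
        net = build_expression_network(m, threshold=0.99)
        assert net.nodes == m.row_ids
        assert net.is_connected()  # spanning-tree completion

    def test_zero_variance_gene_named(self):
        m = make_matrix("mRNA", MatrixKind.CONTINUOUS,
                        [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="g0"):
            build_expression_network(m)


def _oracle_edges(values, genes, thr):
    """Independent oracle: per-pair scipy pearsonr + hand-rolled Kruskal."""
    n = len(genes)
    pairs = {}
    for i in range(n):
        for j in range(i + 1, n):
            pairs[(i, j)] = pearsonr(values[i], values[j]).statistic
    edges = {frozenset((genes[i], genes[j]))
             for (i, j), r in pairs.items() if abs(r) >= thr}
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comp_edges = set(edges)
    # is the thresholded graph connected? if not, add max-|r| spanning tree
    for (i, j), r in pairs.items():
        if frozenset((genes[i], genes[j])) in edges:
            pi, pj = find(i), find(j)
            if pi != pj:
                parent[pi] = pj
    if len({find(i) for i in range(n)}) > 1:
        parent = list(range(n))
        for (i, j), r in sorted(pairs.items(), key=lambda kv: -abs(kv[1])):
            pi, pj = find(i), find(j)
            if pi != pj:
                parent[pi] = pj
                comp_edges.add(frozenset((genes[i], genes[j])))
    return comp_edges


class TestLayoutNetwork:
    def test_single_node_centered(self):
        g = nx.Graph()
        g.add_node("g0")
        net = layout_network(ExpressionNetwork(g), seed=1,
                             canvas=(400, 400), node_spacing=50)
        assert net.positions["g0"] == (200.0, 200.0)

    def test_same_seed_identical_positions(self):
        g = nx.cycle_graph(6)
        a = layout_network(ExpressionNetwork(nx.relabel_nodes(g, str)), 5,
                           (600, 600), 60, margin=50)
        b = layout_network(ExpressionNetwork(nx.relabel_nodes(g, str)), 5,
                           (600, 600), 60, margin=50)
        assert a.positions == b.positions

    def test_cycle_graph_respects_spacing(self):
        g = nx.relabel_nodes(nx.cycle_graph(8), str)
        net = layout_network(ExpressionNetwork(g), seed=2,
                             canvas=(700, 700), node_spacing=80, margin=60)
        pts = list(net.positions.values())
        dmin = min(math.dist(pts[i], pts[j])
                   for i in range(8) for j in range(i + 1, 8))
        assert dmin >= 80 - 1e-6

    def test_impossible_spacing_advises_larger_canvas(self):
        g = nx.relabel_nodes(nx.complete_graph(10), str)
        with pytest.raises(ValueError, match="canvas"):
            layout_network(ExpressionNetwork(g), seed=1,
                           canvas=(120, 120), node_spacing=200, margin=10)


class TestAngular:
    def test_sectors_tile_the_circle(self):
        for s in (1, 3, 4, 7, 30):
            ang = AngularLayout(n_sectors=s)
            widths = [abs(b - a) for a, b in
                      (ang.sector_bounds(k) for k in range(s))]
            assert sum(widths) == pytest.approx(360.0)
            starts = sorted(ang.sector_bounds(k)[0] for k in range(s))
            gaps = {round(b - a, 9) for a, b in zip(starts, starts[1:])}
            assert len(gaps) <= 1  # evenly spaced, no overlap

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(1, 60))
    def test_sector_widths_sum_to_360(self, s):
        ang = AngularLayout(n_sectors=s, direction="counterclockwise")
        total = sum(abs(b - a) for a, b in
                    (ang.sector_bounds(k) for k in range(s)))
        assert total == pytest.approx(360.0)

    def test_four_samples_span_90_degrees_each(self):
        ang = AngularLayout(n_sectors=4)
        a0, a1 = ang.sector_bounds(0)
        assert a0 == 90.0 and a1 == 0.0  # clockwise from 12 o'clock


class TestNodeTracks:
    def test_default_five_tracks_glyph_count(self):
        s = 4
        ds = make_dataset(n_genes=2, n_samples=s, cnv=np.zeros((2, s), dtype=int))
        tracks = default_tracks(40.0)
        glyphs = layout_node_tracks("g0", ds, tracks, AngularLayout(s), (100.0, 100.0))
        filled = [g for g in glyphs if g.kind in ("polygon", "arc_sector")]
        assert len(filled) == 4 * s  # polygon + 2 heatmaps + bar per sample
        assert not [g for g in glyphs if g.tag.startswith("track:point")]

    def test_heatmap_midpoint_neutral(self):
        ds = make_dataset(n_genes=1, n_samples=4)
        ds.matrix("RNASeq").data.iloc[0, :] = 0.0
        glyphs = layout_node_tracks("g0", ds, default_tracks(40.0),
                                    AngularLayout(4), (0.0, 0.0))
        heat = [g for g in glyphs if g.tag == "track:heatmap:RNASeq"]
        assert {g.color for g in heat} == {"#ffffff"}

    def test_radial_containment_and_bar_monotonicity(self):
        ds = make_dataset(n_genes=1, n_samples=6, seed=3)
        tracks = default_tracks(50.0)
        glyphs = layout_node_tracks("g0", ds, tracks, AngularLayout(6), (0.0, 0.0))
        spans = {t.data_name: (t.r_inner, t.r_outer) for t in tracks}
        for g in glyphs:
            name = g.tag.split(":")[-1]
            lo, hi = spans[name]
            if g.kind == "arc_sector":
                assert lo - 1e-9 <= g.coords[2] <= g.coords[3] <= hi + 1e-9
            elif g.kind == "point":
                r = math.hypot(g.coords[0], g.coords[1])
                assert lo <= r <= hi
        # bar length grows with the category code
        methyl = ds.matrix("Methylation")
        bars = [g for g in glyphs if g.tag == "track:bar:Methylation"]
        for k, g in enumerate(bars):
            frac = methyl.values[0][k] / methyl.max_code()
            lo, hi = spans["Methylation"]
            assert g.coords[3] - lo == pytest.approx(frac * (hi - lo))

    def test_overlapping_tracks_rejected(self, small_dataset):
        tracks = [TrackSpec("RNASeq", "heatmap", 10, 30),
                  TrackSpec("miRNASeq", "heatmap", 20, 40)]
        with pytest.raises(ValueError, match="overlap"):
            layout_node_tracks("g0", small_dataset, tracks,
                               AngularLayout(4), (0.0, 0.0))

    def test_unknown_data_name_rejected(self, small_dataset):
        tracks = [TrackSpec("Proteome", "heatmap", 10, 30)]
        with pytest.raises(KeyError, match="Proteome"):
            layout_node_tracks("g0", small_dataset, tracks,
                               AngularLayout(4), (0.0, 0.0))


class TestSampleLinks:
    def test_empty_pairs_empty_glyphs(self):
        assert layout_sample_links("g", [], AngularLayout(4), (0, 0), 8,
                                   ["s0", "s1", "s2", "s3"]) == []

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="s0"):
            layout_sample_links("g", [("s0", "s0")], AngularLayout(4), (0, 0), 8,
                                ["s0", "s1", "s2", "s3"])

    def test_chord_endpoints_on_inner_circle(self):
        samples = ["s0", "s1", "s2", "s3"]
        glyphs = layout_sample_links("g", [("s0", "s2"), ("s1", "s3")],
                                     AngularLayout(4), (10.0, 20.0), 8.0, samples)
        assert len(glyphs) == 2
        for g in glyphs:
            for x, y in ((g.coords[0], g.coords[1]), (g.coords[2], g.coords[3])):
                assert math.hypot(x - 10.0, y - 20.0) == pytest.approx(8.0)

    def test_unknown_sample_rejected(self):
        with pytest.raises(KeyError, match="sX"):
            layout_sample_links("g", [("s0", "sX")], AngularLayout(2), (0, 0), 5,
                                ["s0", "s1"])


class TestLabels:
    def _net(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "bb", "ccc"])
        return ExpressionNetwork(g, {"a": (100.0, 100.0), "bb": (200.0, 100.0),
                                     "ccc": (150.0, 220.0)})

    def test_default_placement_under_nodes(self):
        net = self._net()
        glyphs = place_labels(net, node_radius=30.0)
        assert len(glyphs) == 3
        for g in glyphs:
            assert g.coords[1] > net.positions[g.text][1]

    def test_override_above_moves_only_that_label(self):
        net = self._net()
        glyphs = place_labels(net, node_radius=30.0, overrides={"bb": "above"})
        for g in glyphs:
            if g.text == "bb":
                assert g.coords[1] < net.positions["bb"][1]
            else:
                assert g.coords[1] > net.positions[g.text][1]


class TestCompose:
    def test_scene_accounting_and_connectivity(self):
        g_n, s_n = 4, 6
        ds = make_dataset(n_genes=g_n, n_samples=s_n,
                          cnv=np.zeros((g_n, s_n), dtype=int))
        sc = compose_bionetcircos(ds, BioNetParams(seed=3))
        filled = [g for g in sc.glyphs
                  if g.tag.startswith("track") and g.kind in ("polygon", "arc_sector")]
        assert len(filled) == 4 * g_n * s_n
        assert sc.count("node_label") == g_n
        assert sc.count("edge") >= g_n - 1  # connected
        assert sc.in_bounds(), sc.out_of_bounds_glyphs()

    def test_two_runs_same_seed_byte_identical(self, small_dataset):
        p = BioNetParams(seed=11)
        a = scene_to_svg(compose_bionetcircos(small_dataset, p))
        b = scene_to_svg(compose_bionetcircos(small_dataset, p))
        assert a == b

    def test_two_genes_connected_with_labels(self):
        ds = make_dataset(n_genes=2, n_samples=5)
        sc = compose_bionetcircos(ds, BioNetParams(seed=1))
        assert sc.count("node_label") == 2
        assert sc.count("edge") >= 1  # spanning-tree completion

    def test_explicit_edges_bypass_inference(self):
        ds = make_dataset(n_genes=3, n_samples=5)
        p = BioNetParams(seed=2, edges=[("g0", "g1")])
        sc = compose_bionetcircos(ds, p)
        assert sc.count("edge") == 1

    @settings(derandomize=True, max_examples=8, deadline=None)
    @given(st.integers(2, 12), st.integers(3, 20))
    def test_in_bounds_for_randomized_sizes(self, g_n, s_n):
        ds = make_dataset(n_genes=g_n, n_samples=s_n, seed=g_n * 100 + s_n)
        sc = compose_bionetcircos(ds, BioNetParams(seed=4))
        assert sc.in_bounds(), sc.out_of_bounds_glyphs()


class TestLegend:
    def test_five_printed_data_names_in_order(self):
        glyphs = bionet_legend()
        keys = [g.text for g in glyphs if g.tag == "legend:key"]
        assert keys == ["1. Tissue Type", "2. RNASeq", "3. miRNASeq",
                        "4. Methylation", "5. CNV"]
        texts = {g.text for g in glyphs if g.kind == "text"}
        assert {"-3", "3"} <= texts

    def test_single_name_still_has_ramp(self):
        glyphs = bionet_legend(("RNASeq",))
        assert len([g for g in glyphs if g.tag == "legend:key"]) == 1
        assert [g for g in glyphs if g.tag == "legend:ramp"]
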