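"""Similarity coefficients, term network, tiled layout, barcode, hexbin."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import omicrate as oc
from omicrate.errors import EmptySetError, TermNotTestedError, UnknownTargetError
from omicrate.netviz import hexbin_aggregate


class TestTermSimilarity:
    def test_hand_computed_closed_forms(self):
        a, b = set(range(4)), set(range(2, 8))  # |A|=4, |B|=6, |A∩B|=2
        assert oc.term_similarity(a, b, "jaccard") == 0.25
        assert oc.term_similarity(a, b, "overlap") == 0.5
        assert oc.term_similarity(a, b, "combined", k=0.5) == 0.375

    def test_identity_and_disjoint(self):
        a = {1, 2, 3}
        for metric in ("jaccard", "overlap", "combined"):
            assert oc.term_similarity(a, a, metric) == 1.0
            assert oc.term_similarity(a, {9, 10}, metric) == 0.0

    def test_combined_endpoints_recover_j_and_o(self):
        a, b = {1, 2, 3, 4}, {3, 4, 5}
        j = oc.term_similarity(a, b, "jaccard")
        o = oc.term_similarity(a, b, "overlap")
        assert oc.term_similarity(a, b, "combined", k=0.0) == j
        assert oc.term_similarity(a, b, "combined", k=1.0) == o

    def test_empty_sets_and_bad_k_rejected(self):
        with pytest.raises(EmptySetError):
            oc.term_similarity(set(), {1})
        with pytest.raises(ValueError):
            oc.term_similarity({1}, {2}, "combined", k=1.5)

    @given(st.frozensets(st.integers(0, 40), min_size=1, max_size=25),
           st.frozensets(st.integers(0, 40), min_size=1, max_size=25))
    def test_overlap_dominates_jaccard_and_both_symmetric(self, a, b):
        j, o = oc.term_similarity(a, b, "jaccard"), oc.term_similarity(a, b, "overlap")
        assert 0.0 <= j <= o <= 1.0
        assert j == oc.term_similarity(b, a, "jaccard")
        assert o == oc.term_similarity(b, a, "overlap")


def union_find_components(nodes, edges):
    """Independent component oracle: naive union-find over all pairs."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted((sorted(g) for g in groups.values()), key=lambda c: (-len(c), c[0]))


def two_term_study(shared_all=True):
    s = oc.create_study("net")
    df = pd.DataFrame({"feature_id": [f"f{i}" for i in range(6)],
                       "t": [1.0] * 6, "p_value": [0.5] * 6, "adj_p_value": [0.5] * 6})
    s.add_results("M", "T1", df)
    feats = ["f0", "f1", "f2"] if shared_all else ["f3", "f4"]
    db = oc.AnnotationDatabase("db", {"termA": ["f0", "f1", "f2"], "termB": feats})
    enr = pd.DataFrame([("termA", "T1", 0.001, 0.01), ("termB", "T1", 0.002, 0.02)],
                       columns=["term_id", "test", "nominal", "adjusted"])
    s.add_enrichments("M", db, enr)
    return s


class TestBuildNetwork:
    def test_terms_sharing_all_features_form_one_cluster(self):
        net = oc.build_network(two_term_study(), "M", "db")
        assert len(net.nodes) == 2 and len(net.edges) == 1
        assert net.edges[0].jaccard == 1.0
        assert net.clusters == [["termA", "termB"]]

    def test_impossible_edge_cutoff_gives_all_singletons(self):
        net = oc.build_network(two_term_study(), "M", "db", edge_cutoff=1.01)
        assert net.edges == [] and net.n_clusters == 2

    def test_no_passing_terms_returns_empty_network_with_warning(self):
        net = oc.build_network(two_term_study(), "M", "db", node_cutoff=1e-6)
        assert net.nodes == {} and net.warning

    def test_node_size_counts_tested_features_only(self, demo_study):
        """Size is |term ∩ tested universe|, never the raw database term size."""
        s = oc.create_study("partial")
        df = pd.DataFrame({"feature_id": ["f0", "f1"], "t": [1.0, 2.0],
                           "p_value": [0.5, 0.5], "adj_p_value": [0.5, 0.5]})
        s.add_results("M", "T1", df)
        db = oc.AnnotationDatabase("db", {"termA": ["f0", "f1", "untested1", "untested2"]})
        enr = pd.DataFrame([("termA", "T1", 0.001, 0.01)],
                           columns=["term_id", "test", "nominal", "adjusted"])
        s.add_enrichments("M", db, enr)
        net = oc.build_network(s, "M", "db")
        assert net.nodes["termA"].size == 2

    def test_each_node_carries_one_wedge_per_stored_test(self, demo_study):
        net = oc.build_network(demo_study, "Differential_Expression",
                               "synthetic_pathways", node_cutoff=0.25)
        assert net.nodes
        for node in net.nodes.values():
            assert [w["test"] for w in node.wedges] == ["BasalvsLP", "BasalvsML", "LPvsML"]

    def test_components_match_union_find_oracle(self, demo_study):
        for cutoff in (0.05, 0.25, 0.5):
            net = oc.build_network(demo_study, "Differential_Expression",
                                   "synthetic_pathways", node_cutoff=0.5,
                                   edge_cutoff=cutoff)
            oracle = union_find_components(
                list(net.nodes), [(e.source, e.target) for e in net.edges])
            assert net.clusters == oracle

    def test_raising_edge_cutoff_never_merges_clusters(self, demo_study):
        counts = []
        for cutoff in np.linspace(0.0, 1.05, 12):
            net = oc.build_network(demo_study, "Differential_Expression",
                                   "synthetic_pathways", node_cutoff=0.5,
                                   edge_cutoff=float(cutoff))
            counts.append(net.n_clusters)
        assert counts == sorted(counts)

    def test_unknown_database_raises(self, demo_study):
        with pytest.raises(UnknownTargetError):
            oc.build_network(demo_study, "Differential_Expression", "ghost")


class TestTiledLayout:
    @staticmethod
    def synthetic_network(cluster_specs):
        """Build a TermNetwork directly: [(n_nodes, min_p), ...]."""
        from omicrate.netviz import TermEdge, TermNetwork, TermNode

        nodes, edges, clusters = {}, [], []
        for ci, (size, min_p) in enumerate(cluster_specs):
            ids = [f"c{ci}n{j}" for j in range(size)]
            for j, tid in enumerate(ids):
                p = min_p if j == 0 else min(1.0, min_p * 10)
                nodes[tid] = TermNode(tid, tid, 5, [{"test": "T", "nominal": p,
                                                     "adjusted": p}])
            edges += [TermEdge(a, b, 1.0, 1.0, 1.0, 1.0)
                      for a, b in zip(ids, ids[1:])]
            clusters.append(sorted(ids))
        return TermNetwork(nodes, edges, clusters, "jaccard", 0.25, 0.05)

    def test_node_count_order_largest_first(self):
        net = self.synthetic_network([(5, 0.01), (3, 0.001), (1, 0.0001)])
        layout = oc.tiled_layout(net, "node_count")
        assert [len(c) for c in layout.cluster_order] == [5, 3, 1]

    def test_min_p_breaks_equal_size_ties(self):
        net = self.synthetic_network([(2, 1e-3), (2, 1e-8)])
        layout = oc.tiled_layout(net, "min_p")
        assert layout.cluster_order[0][0].startswith("c1")

    def test_tiles_fill_top_to_bottom_then_left_to_right(self):
        net = self.synthetic_network([(3, 0.01), (2, 0.01), (2, 0.02), (1, 0.01), (1, 0.02)])
        layout = oc.tiled_layout(net, "node_count")
        rows = [t[0] for t in layout.tiles]
        cols = [t[1] for t in layout.tiles]
        assert rows == [0, 1, 2, 0, 1] and cols == [0, 0, 0, 1, 1]

    def test_order_matches_independent_sort_oracle(self, demo_study):
        net = oc.build_network(demo_study, "Differential_Expression",
                               "synthetic_pathways", node_cutoff=0.5, edge_cutoff=0.1)
        for key in ("node_count", "edge_count", "min_p"):
            layout = oc.tiled_layout(net, key)
            stats = []
            for members in net.clusters:
                stats.append({
                    "members": sorted(members),
                    "node_count": len(members),
                    "edge_count": net.cluster_edges(members),
                    "min_p": min(net.nodes[t].min_adjusted() for t in members),
                })
            if key == "node_count":
                stats.sort(key=lambda s: (-s["node_count"], s["min_p"], s["members"][0]))
            elif key == "edge_count":
                stats.sort(key=lambda s: (-s["edge_count"], -s["node_count"], s["members"][0]))
            else:
                stats.sort(key=lambda s: (s["min_p"], -s["node_count"], s["members"][0]))
            assert [sorted(c) for c in layout.cluster_order] == \
                [s["members"] for s in stats]

    def test_unknown_sort_key_rejected(self):
        net = self.synthetic_network([(1, 0.01)])
        with pytest.raises(ValueError):
            oc.tiled_layout(net, "ghost")


class TestBarcode:
    def test_entries_sorted_descending_with_rank_permutation(self):
        s = oc.create_study("bc")
        df = pd.DataFrame({"feature_id": ["f1", "f2", "f3"],
                           "t": [2.0, -5.0, 1.0],
                           "p_value": [0.1, 0.01, 0.5], "adj_p_value": [0.2, 0.05, 0.6]})
        s.add_results("M", "T", df)
        db = oc.AnnotationDatabase("db", {"term": ["f1", "f2", "f3"]})
        s.add_enrichments("M", db, pd.DataFrame(
            [("term", "T", 0.01, 0.05)], columns=["term_id", "test", "nominal", "adjusted"]))
        bc = oc.barcode_data(s, "M", "db", "term", "T")
        assert bc.entries["feature_id"].tolist() == ["f2", "f1", "f3"]
        assert bc.entries["statistic"].tolist() == [5.0, 2.0, 1.0]
        assert bc.ranks() == [1, 2, 3]

    def test_fixture_ranks_are_sort_permutation(self, demo_study):
        bc = oc.barcode_data(demo_study, "Differential_Expression",
                             "synthetic_pathways", "term_0000", "BasalvsLP")
        vals = bc.entries["statistic"].to_numpy()
        assert sorted(bc.ranks()) == list(range(1, len(vals) + 1))
        assert (np.diff(vals) <= 0).all()

    def test_monotone_transform_preserves_order(self, demo_study):
        df = demo_study.model("Differential_Expression").tests["BasalvsLP"].results.df
        s = oc.create_study("scaled")
        scaled = df.copy()
        scaled["t"] = scaled["t"] * 2.0
        s.add_results("Differential_Expression", "BasalvsLP", scaled)
        db = demo_study.annotations["synthetic_pathways"]
        enr = oc.get_enrichments(demo_study, "Differential_Expression",
                                 "synthetic_pathways", test="BasalvsLP")
        s.add_enrichments("Differential_Expression", db, enr)
        a = oc.barcode_data(demo_study, "Differential_Expression", "synthetic_pathways",
                            "term_0003", "BasalvsLP")
        b = oc.barcode_data(s, "Differential_Expression", "synthetic_pathways",
                            "term_0003", "BasalvsLP")
        assert a.entries["feature_id"].tolist() == b.entries["feature_id"].tolist()
        assert a.ranks() == b.ranks()

    def test_single_feature_term_has_degenerate_box(self):
        s = oc.create_study("bc1")
        df = pd.DataFrame({"feature_id": ["f1", "f2"], "t": [3.0, 1.0],
                           "p_value": [0.1, 0.2], "adj_p_value": [0.2, 0.3]})
        s.add_results("M", "T", df)
        db = oc.AnnotationDatabase("db", {"term": ["f1"]})
        s.add_enrichments("M", db, pd.DataFrame(
            [("term", "T", 0.01, 0.05)], columns=["term_id", "test", "nominal", "adjusted"]))
        bc = oc.barcode_data(s, "M", "db", "term", "T")
        assert len(bc.entries) == 1
        assert bc.box["min"] == bc.box["q1"] == bc.box["median"] \
            == bc.box["q3"] == bc.box["max"] == 3.0

    def test_term_disjoint_from_tested_features_raises(self):
        s = oc.create_study("bc2")
        df = pd.DataFrame({"feature_id": ["f1"], "t": [3.0],
                           "p_value": [0.1], "adj_p_value": [0.2]})
        s.add_results("M", "T", df)
        s.add_annotations(oc.AnnotationDatabase("db", {"term": ["zz"]}))
        with pytest.raises(TermNotTestedError):
            oc.barcode_data(s, "M", "db", "term", "T")

    def test_untested_term_members_counted_not_imputed(self):
        s = oc.create_study("bc3")
        df = pd.DataFrame({"feature_id": ["f1", "f2"], "t": [3.0, 1.0],
                           "p_value": [0.1, 0.2], "adj_p_value": [0.2, 0.3]})
        s.add_results("M", "T", df)
        s.add_annotations(oc.AnnotationDatabase("db", {"term": ["f1", "ghost1", "ghost2"]}))
        bc = oc.barcode_data(s, "M", "db", "term", "T")
        assert len(bc.entries) == 1 and bc.n_excluded == 2


def hexbin_oracle(points, grid):
    """Exhaustive nearest-centre assignment: scan lattice A then B, strict <."""
    nx_, ny_ = grid.gridsize, max(1, round(grid.gridsize / math.sqrt(3)))
    xmin, xmax, ymin, ymax = grid.extent
    xmin, ymin = xmin + grid.cell_width / 2, ymin + grid.cell_height / 2
    dx, dy = grid.cell_width, grid.cell_height
    counts = {}
    for x, y in points:
        u, v = (x - xmin) / dx, (y - ymin) / dy
        best, best_d = None, None
        for lat, imax, jmax, off in ((0, nx_, ny_, 0.0), (1, nx_ - 1, ny_ - 1, 0.5)):
            for i in range(imax + 1):
                for j in range(jmax + 1):
                    d = (u - i - off) ** 2 + 3.0 * (v - j - off) ** 2
                    if best_d is None or d < best_d:
                        best, best_d = (lat, i, j), d
        counts[best] = counts.get(best, 0) + 1
    return counts


class TestHexbin:
    def test_single_point_single_cell(self):
        grid = hexbin_aggregate([(1.0, 2.0)], gridsize=5)
        assert len(grid.counts) == 1 and grid.total == 1

    def test_identical_points_share_one_cell(self):
        grid = hexbin_aggregate([(0.5, 0.5)] * 7, gridsize=10)
        assert len(grid.counts) == 1 and grid.total == 7

    def test_counts_conserved_and_nonfinite_dropped(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(500, 2))
        pts[10] = (np.nan, 1.0)
        pts[20] = (np.inf, 0.0)
        grid = hexbin_aggregate(pts, gridsize=15)
        assert grid.n_dropped == 2
        assert grid.total + grid.n_dropped == 500

    @pytest.mark.parametrize("seed,gridsize,n", [(0, 7, 300), (1, 12, 500)])
    def test_assignment_matches_exhaustive_oracle(self, seed, gridsize, n):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-3, 3, size=(n, 2))
        grid = hexbin_aggregate(pts, gridsize=gridsize)
        oracle = hexbin_oracle(pts, grid)
        got = {tuple(map(int, cell)): int(count)
               for cell, count in zip(grid.cells, grid.counts)}
        assert got == oracle

    def test_gridsize_below_one_rejected(self):
        with pytest.raises(ValueError):
            hexbin_aggregate([(0, 0)], gridsize=0)

    def test_members_partition_inputs(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(200, 2))
        grid = hexbin_aggregate(pts, gridsize=8, keep_members=True)
        all_members = sorted(itertools.chain.from_iterable(grid.members))
        assert all_members == list(range(200))
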