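import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import networkx as nx

from episnet import (DegreeDistribution, PairWeightTable, build_graph,
                     connected_components, degree_distribution,
                     filter_significant, threshold_grid, threshold_sweep)
from episnet.network import (read_graphml, write_dot, write_edge_tsv,
                             write_graphml, write_vertex_tsv)
from conftest import TABLE1_N_VERTICES, TABLE1_REAL_PD


def table_from_dict(ids, weight_map, p_map=None):
    m = len(ids)
    tab = PairWeightTable(snp_ids=list(ids),
                          weights=np.full(m * (m - 1) // 2, -np.inf))
    if p_map is not None:
        tab.p_values = np.ones(tab.n_pairs)
    pos = {s: k for k, s in enumerate(ids)}
    for (a, b), w in weight_map.items():
        tab.weights[tab.index(pos[a], pos[b])] = w
        if p_map is not None:
            tab.p_values[tab.index(pos[a], pos[b])] = p_map[(a, b)]
    return tab


class TestBuildGraph:
    WEIGHTS = {("A", "B"): 0.5, ("B", "C"): 0.4, ("C", "D"): 0.1}

    def test_threshold_selects_edges_and_vertices(self):
        tab = table_from_dict("ABCD", self.WEIGHTS)
        g = build_graph(tab, None, 0.4)
        assert set(map(frozenset, g.edges)) == {frozenset("AB"),
                                               frozenset("BC")}
        assert set(g.nodes) == {"A", "B", "C"}  # D has no incident edge

    def test_above_max_weight_gives_empty_graph(self):
        tab = table_from_dict("ABCD", self.WEIGHTS)
        g = build_graph(tab, None, 0.6)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_minus_inf_gives_complete_graph(self):
        tab = table_from_dict("ABCD", self.WEIGHTS)
        g = build_graph(tab, None, -np.inf)
        assert g.number_of_edges() == 6 and g.number_of_nodes() == 4

    def test_tie_at_threshold_included(self):
        tab = table_from_dict("ABCD", self.WEIGHTS)
        assert ("C", "D") in build_graph(tab, None, 0.1).edges

    def test_vertex_weights_attached(self):
        import pandas as pd
        tab = table_from_dict("ABCD", self.WEIGHTS)
        mains = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("ABCD"))
        g = build_graph(tab, mains, 0.4)
        assert g.nodes["B"]["mutual_information"] == 0.2


class TestFilterSignificant:
    def _graph(self, p_map):
        tab = table_from_dict("ABCD", self.WEIGHTS, p_map)
        return build_graph(tab, None, 0.0)

    WEIGHTS = {("A", "B"): 0.5, ("B", "C"): 0.4, ("C", "D"): 0.1}

    def test_all_significant_is_identity(self):
        g = self._graph({k: 0.0 for k in self.WEIGHTS})
        h = filter_significant(g, 0.01)
        assert set(h.edges) == set(g.edges) and set(h.nodes) == set(g.nodes)

    def test_none_significant_empties_graph(self):
        g = self._graph({k: 1.0 for k in self.WEIGHTS})
        h = filter_significant(g, 0.01)
        assert h.number_of_nodes() == 0

    def test_idempotent_and_drops_isolated(self):
        p = {("A", "B"): 0.001, ("B", "C"): 0.5, ("C", "D"): 0.001}
        h = filter_significant(self._graph(p), 0.01)
        assert set(h.nodes) == {"A", "B", "C", "D"}
        p2 = {("A", "B"): 0.001, ("B", "C"): 0.5, ("C", "D"): 0.9}
        h2 = filter_significant(self._graph(p2), 0.01)
        assert set(h2.nodes) == {"A", "B"}
        again = filter_significant(h2, 0.01)
        assert set(again.edges) == set(h2.edges)

    def test_alpha_one_keeps_everything(self):
        g = self._graph({k: 1.0 for k in self.WEIGHTS})
        assert filter_significant(g, 1.0).number_of_edges() == 3

    def test_missing_pvalue_is_error(self):
        tab = table_from_dict("ABCD", self.WEIGHTS)
        g = build_graph(tab, None, 0.0)
        with pytest.raises(ValueError, match="p_value"):
            filter_significant(g, 0.01)


class TestThresholdGrid:
    def test_default_grid_has_21_points_ending_at_zero(self):
        grid = threshold_grid(0.02, 0.0, 0.001)
        assert grid.size == 21
        assert grid[0] == pytest.approx(0.02)
        assert grid[-1] == 0.0
        assert (np.diff(grid) < 0).all()

    def test_invalid_grids(self):
        with pytest.raises(ValueError):
            threshold_grid(0.0, 0.02, 0.001)
        with pytest.raises(ValueError):
            threshold_grid(0.02, 0.0, 0.0)


class TestThresholdSweep:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_independent_build_and_nests(self, seed):
        rng = np.random.default_rng(seed)
        m = 10
        tab = PairWeightTable(
            snp_ids=[f"s{k}" for k in range(m)],
            weights=rng.uniform(-0.005, 0.025, size=m * (m - 1) // 2))
        sweep = threshold_sweep(tab, 0.02, 0.0, 0.002)
        prev_edges = -1
        prev_vertices = -1
        for gi, t in enumerate(sweep.thresholds):
            g = build_graph(tab, None, float(t))
            assert g.number_of_edges() == sweep.n_edges[gi]
            assert g.number_of_nodes() == sweep.n_vertices[gi]
            comps = connected_components(g)
            assert (len(comps[0]) if comps else 0) == sweep.lcc_size[gi]
            assert sorted((len(c) for c in comps), reverse=True) == \
                sweep.component_sizes[gi]
            # monotone nesting as t decreases
            assert sweep.n_edges[gi] >= prev_edges
            assert sweep.n_vertices[gi] >= prev_vertices
            prev_edges, prev_vertices = sweep.n_edges[gi], sweep.n_vertices[gi]
            # component sizes partition the vertex set
            assert sum(sweep.component_sizes[gi]) == sweep.n_vertices[gi]

    def test_single_edge_appears_at_its_weight(self):
        tab = table_from_dict("ABC", {("A", "B"): 0.0103})
        sweep = threshold_sweep(tab, 0.02, 0.0, 0.001)
        jumps = np.flatnonzero(sweep.n_edges == 1)
        assert sweep.thresholds[jumps[0]] == pytest.approx(0.010)


class TestConnectedComponents:
    def test_two_disjoint_edges(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        comps = connected_components(g)
        assert [len(c) for c in comps] == [2, 2]
        assert comps[0] == {"A", "B"}  # tie broken by smallest member

    def test_path_and_star(self):
        assert [len(c) for c in
                connected_components(nx.path_graph(["A", "B", "C"]))] == [3]
        star = nx.star_graph(5)
        assert [len(c) for c in connected_components(star)] == [6]


class TestDegreeDistribution:
    def test_star_k13(self):
        g = nx.star_graph(3)
        dd = degree_distribution(g)
        assert dd.p(1) == 0.75 and dd.p(3) == 0.25
        assert dd.n_edges == 3

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_handshake_lemma_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(15, 0.3, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() == 0:
            return
        dd = degree_distribution(g)
        assert sum(d * n for d, n in dd.counts.items()) == \
            2 * g.number_of_edges()
        assert sum(dd.counts.values()) == g.number_of_nodes()

    def test_reconstructs_printed_distribution(self):
        dd = DegreeDistribution.from_probabilities(TABLE1_REAL_PD,
                                                   TABLE1_N_VERTICES)
        assert [dd.counts[d] for d in sorted(dd.counts)] == \
            [216, 64, 17, 11, 4, 4, 2, 1]
        assert sum(d * n for d, n in dd.counts.items()) == 510
        assert dd.n_edges == 255

    def test_rejects_degree_zero_and_bad_totals(self):
        with pytest.raises(ValueError):
            DegreeDistribution(counts={0: 1, 1: 2}, n_vertices=3)
        with pytest.raises(ValueError):
            DegreeDistribution(counts={1: 2}, n_vertices=3)


class TestExports:
    def _graph(self):
        import pandas as pd
        tab = table_from_dict("ABC", {("A", "B"): 0.012, ("B", "C"): 0.015},
                              {("A", "B"): 0.001, ("B", "C"): 0.002})
        mains = pd.Series([0.001, 0.004, 0.002], index=list("ABC"))
        return build_graph(tab, mains, 0.01)

    def test_tsv_exports(self, tmp_path):
        import pandas as pd
        g = self._graph()
        write_edge_tsv(g, tmp_path / "e.tsv", header_comment="prov")
        write_vertex_tsv(g, tmp_path / "v.tsv", header_comment="prov")
        edges = pd.read_csv(tmp_path / "e.tsv", sep="\t", comment="#")
        verts = pd.read_csv(tmp_path / "v.tsv", sep="\t", comment="#")
        assert len(edges) == 2 and len(verts) == 3
        assert "p_value" in edges.columns

    def test_graphml_roundtrip(self, tmp_path):
        g = self._graph()
        write_graphml(g, tmp_path / "g.graphml")
        back = read_graphml(tmp_path / "g.graphml")
        assert set(back.nodes) == set(g.nodes)
        assert back.edges["A", "B"]["information_gain"] == pytest.approx(
            0.012)

    def test_dot_records_scaling(self, tmp_path):
        g = self._graph()
        write_dot(g, tmp_path / "g.dot")
        text = (tmp_path / "g.dot").read_text()
        assert "penwidth" in text and "// vertex width" in text
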