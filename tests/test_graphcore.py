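import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netvuln as nv
from netvuln.graphcore import lcc_sizes_after_edge_removals, lcc_sizes_after_node_removals

from conftest import (
    brute_lcc_sizes_edge_removal,
    brute_lcc_sizes_node_removal,
    eq6_modularity,
    set_partitions,
    two_joined_triangles,
)


def gnp(n, p, seed):
    return nx.gnp_random_graph(n, p, seed=seed)


class TestLargestConnectedComponent:
    def test_two_triangles_plus_isolate(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        g.add_node(6)
        sub, size = nv.largest_connected_component(g)
        assert size == 3
        # equal-size tie broken by the smallest sorted identifier sequence
        assert set(sub.nodes()) == {0, 1, 2}

    def test_connected_path(self):
        _, size = nv.largest_connected_component(nx.path_graph(5))
        assert size == 5

    def test_edgeless(self):
        g = nx.empty_graph(4)
        _, size = nv.largest_connected_component(g)
        assert size == 1


class TestDistanceSummary:
    def test_path3(self):
        asp, diam, eff = nv.distance_summary(nx.path_graph(["a", "b", "c"]))
        assert asp == pytest.approx(8 / 6)
        assert diam == 2
        assert eff == pytest.approx(5 / 6)

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_complete(self, n):
        asp, diam, eff = nv.distance_summary(nx.complete_graph(n))
        assert (asp, diam, eff) == (1.0, 1, 1.0)

    def test_karate(self, karate):
        asp, diam, _ = nv.distance_summary(karate)
        assert asp == pytest.approx(2.408, abs=1e-3)
        assert diam == 5

    def test_singleton_lcc(self):
        g = nx.empty_graph(3)
        asp, diam, eff = nv.distance_summary(g)
        assert (asp, diam, eff) == (0.0, 0, 0.0)

    def test_lcc_equals_extracted_component(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 3), (5, 6)])
        sub, _ = nv.largest_connected_component(g)
        assert nv.distance_summary(g)[:2] == nv.distance_summary(sub)[:2]

    def test_efficiency_edgeless_zero(self):
        assert nv.distance_summary(nx.empty_graph(5))[2] == 0.0


class TestScalarIndicators:
    def test_star_assortativity(self):
        assert nv.degree_assortativity(nx.star_graph(3)) == pytest.approx(-1.0)

    def test_cycle_assortativity_undefined(self):
        with pytest.raises(nv.UndefinedIndicatorError):
            nv.degree_assortativity(nx.cycle_graph(5))

    def test_karate_assortativity(self, karate):
        assert nv.degree_assortativity(karate) == pytest.approx(-0.476, abs=1e-3)

    @pytest.mark.parametrize(
        "g,expect",
        [
            (nx.complete_graph(5), 1.0),
            (nx.empty_graph(4), 0.0),
            (nx.path_graph(4), 0.5),
        ],
    )
    def test_density(self, g, expect):
        assert nv.density(g) == pytest.approx(expect)

    def test_density_karate(self, karate):
        assert nv.density(karate) == pytest.approx(156 / 1122, abs=1e-9)

    def test_density_single_node(self):
        with pytest.raises(ValueError):
            nv.density(nx.empty_graph(1))

    def test_transitivity(self, karate):
        assert nv.transitivity(nx.cycle_graph(3)) == 1.0
        assert nv.transitivity(nx.random_labeled_tree(8, seed=1)) == 0.0
        assert nv.transitivity(karate) == pytest.approx(0.256, abs=1e-3)


class TestModularity:
    def test_complete_graph_single_community_zero(self):
        g = nx.complete_graph(5)
        part = nv.CommunityPartition({v: 0 for v in g})
        assert nv.modularity_value(g, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_partition_matches_exhaustive(self):
        g = two_joined_triangles()
        planted = [{0, 1, 2}, {3, 4, 5}]
        val = nv.modularity_value(g, planted)
        assert val == pytest.approx(eq6_modularity(g, planted), abs=1e-12)
        best = max(eq6_modularity(g, p) for p in set_partitions(list(g.nodes())))
        _, found = nv.community_modularity(g)
        assert found == pytest.approx(best, abs=1e-12)

    def test_karate(self, karate):
        part, mod = nv.community_modularity(karate)
        assert mod == pytest.approx(0.381, abs=5e-3)
        assert set(part.membership) == set(karate.nodes())

    def test_louvain_switch_runs(self, karate):
        part, mod = nv.community_modularity(karate, seed=1, method="louvain")
        assert 0.3 < mod < 0.5

    def test_edgeless_error(self):
        with pytest.raises(ValueError):
            nv.community_modularity(nx.empty_graph(3))

    @pytest.mark.parametrize("seed", range(4))
    def test_eq6_evaluation_matches_oracle_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        g = gnp(7, 0.5, seed)
        if g.number_of_edges() == 0:
            pytest.skip("empty draw")
        labels = rng.integers(0, 3, g.number_of_nodes())
        comms = [
            {v for v, l in zip(g.nodes(), labels) if l == c}
            for c in range(3)
            if (labels == c).any()
        ]
        assert nv.modularity_value(g, comms) == pytest.approx(
            eq6_modularity(g, comms), abs=1e-12
        )


class TestIndicatorProfile:
    def test_complete_k5(self):
        p = nv.indicator_profile(nx.complete_graph(5))
        assert p.density == 1.0 and p.transitivity == 1.0
        assert p.efficiency == 1.0 and p.diameter == 1.0

    def test_karate_matches_table_row(self, karate):
        p = nv.indicator_profile(karate)
        assert (p.n, p.m) == (34, 78)
        assert p.asp == pytest.approx(2.408, abs=1e-3)
        assert p.assortativity == pytest.approx(-0.476, abs=1e-3)
        assert p.density == pytest.approx(0.139, abs=1e-3)
        assert p.modularity == pytest.approx(0.381, abs=5e-3)
        assert p.transitivity == pytest.approx(0.256, abs=1e-3)
        assert p.diameter == 5

    def test_two_node_edge(self):
        p = nv.indicator_profile(nx.path_graph(2))
        assert (p.asp, p.diameter, p.density, p.transitivity) == (1.0, 1.0, 1.0, 0.0)
        # 1-regular: assortativity is flagged missing, not reported as zero
        assert math.isnan(p.assortativity)
        assert "assortativity_undefined" in p.flags

    def test_profiles_frame_columns(self, karate):
        frame = nv.profiles_to_frame({"karate": nv.indicator_profile(karate)})
        assert list(frame.columns) == ["name", "N", "E", "ASP", "r", "D", "d", "M", "T"]


class TestRobustnessCurve:
    def test_triangle_node_any_order(self):
        g = nx.cycle_graph(3)
        import itertools

        for order in itertools.permutations(g.nodes()):
            c = nv.robustness_curve(g, list(order), mode="node")
            assert np.allclose(c.S, [2 / 3, 1 / 3, 0.0])
            assert c.index == pytest.approx(1 / 3)

    def test_star5_degree_order(self):
        g = nx.star_graph(4)
        t = nv.rank_nodes(g, "degree")
        c = nv.robustness_curve(g, list(t.order), mode="node")
        assert np.allclose(c.S, [1 / 5] * 4 + [0.0])
        assert c.index == pytest.approx(0.16)

    def test_triangle_edges(self):
        g = nx.cycle_graph(3)
        c = nv.robustness_curve(g, list(g.edges()), mode="edge")
        assert np.allclose(c.S, [1.0, 2 / 3, 1 / 3])
        assert c.index == pytest.approx(2 / 3)

    @pytest.mark.parametrize("c", [3, 5, 8])
    def test_complete_graph_closed_form(self, c):
        g = nx.complete_graph(c)
        curve = nv.robustness_curve(g, list(g.nodes()), mode="node")
        expect = sum((c - j) / c for j in range(1, c + 1)) / c
        assert curve.index == pytest.approx(expect)

    def test_not_a_permutation(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError):
            nv.robustness_curve(g, [0, 1, 2], mode="node")
        with pytest.raises(ValueError):
            nv.robustness_curve(g, [0, 0, 1, 2], mode="node")

    @pytest.mark.parametrize("seed", range(3))
    def test_union_find_matches_brute_force(self, seed):
        g = gnp(12, 0.25, seed)
        rng = np.random.default_rng(seed)
        nodes = list(g.nodes())
        order = [nodes[i] for i in rng.permutation(len(nodes))]
        assert lcc_sizes_after_node_removals(g, order) == brute_lcc_sizes_node_removal(g, order)
        if g.number_of_edges() > 0:
            edges = [tuple(sorted(e, key=str)) for e in g.edges()]
            eorder = [edges[i] for i in rng.permutation(len(edges))]
            assert lcc_sizes_after_edge_removals(g, eorder) == brute_lcc_sizes_edge_removal(
                g, eorder
            )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=20),
    p=st.floats(min_value=0.0, max_value=1.0),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_bounded_indicators_on_random_graphs(n, p, seed):
    """Density, transitivity, efficiency and R_n always land in [0, 1]."""
    g = gnp(n, p, seed)
    assert 0.0 <= nv.density(g) <= 1.0
    assert 0.0 <= nv.transitivity(g) <= 1.0
    assert 0.0 <= nv.distance_summary(g)[2] <= 1.0
    curve = nv.robustness_curve(g, sorted(g.nodes()), mode="node")
    assert 0.0 <= curve.index <= 1.0
    assert curve.S[-1] == 0.0
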