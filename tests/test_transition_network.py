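from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnkit import (
    DescriptorSpec,
    TransitionNetwork,
    build_transition_matrix,
    detect_communities,
    export_network,
    generate_markov_series,
    scale_node_sizes,
    summarize_communities,
)
from tnkit.descriptors import DescriptorStateSeries


def series_from_states(states, raw=None):
    states = np.asarray(states, dtype=int)
    n_desc = 3
    if raw is None:
        raw = np.column_stack([states, np.zeros_like(states), 10.0 * states]).astype(float)
    binned = [(int(s), 0, int(s)) for s in states]
    state_map = {}
    for b in binned:
        state_map.setdefault(b, len(state_map))
    # remap to dense first-appearance ids
    dense = {b: i for i, b in enumerate(dict.fromkeys(binned))}
    dense_states = np.array([dense[b] for b in binned])
    return DescriptorStateSeries(np.asarray(raw, dtype=float), binned, dense, dense_states,
                                 DescriptorSpec())


class TestCounting:
    def test_simple_pair_counts(self):
        net = build_transition_matrix(series_from_states([0, 0, 1]))
        assert net.counts[0, 0] == 1 and net.counts[0, 1] == 1
        assert net.counts.sum() == 2

    def test_constant_series(self):
        net = build_transition_matrix(series_from_states([0] * 7))
        assert net.counts[0, 0] == 6 and net.counts.sum() == 6

    def test_no_cross_segment_pairs(self):
        net = build_transition_matrix(series_from_states([0, 1, 1, 0]), segments=[(0, 2), (2, 4)])
        assert net.counts[0, 1] == 1 and net.counts[1, 0] == 1
        assert net.counts[0, 0] == 0 and net.counts[1, 1] == 0

    def test_segment_shorter_than_lag_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            build_transition_matrix(series_from_states([0, 1, 0, 1]), segments=[(0, 2), (2, 4)], lag=2)

    @given(
        states=st.lists(st.integers(0, 4), min_size=4, max_size=60),
        cut=st.integers(1, 3),
        lag=st.integers(1, 2),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_conservation(self, states, cut, lag):
        """Σ matrix entries = Σ_segments (len − lag) for any series/segmentation."""
        n = len(states)
        if n >= 2 * (lag + 1):
            split = max(lag + 1, min(n - lag - 1, cut * n // 4))
            segments = [(0, split), (split, n)]
        else:
            segments = [(0, n)]
        series = series_from_states(states)
        net = build_transition_matrix(series, segments, lag=lag)
        assert net.counts.sum() == sum((e - s) - lag for s, e in segments)

    def test_markov_matrix_recovery(self):
        """Row-normalized counts approach the generating matrix within
        3·√(P(1−P)/row visits) on a 10⁵-step chain."""
        P = np.array([[0.90, 0.08, 0.02], [0.05, 0.90, 0.05], [0.10, 0.20, 0.70]])
        states = generate_markov_series(P, 100_000, seed=11)
        net = build_transition_matrix(series_from_states(states))
        # map dense ids back to macrostate values
        order = [int(states[np.nonzero(net.series.states == i)[0][0]]) for i in range(3)]
        row_sums = net.counts.sum(axis=1, keepdims=True)
        P_hat = net.counts / row_sums
        for i in range(3):
            for j in range(3):
                p = P[order[i], order[j]]
                se = np.sqrt(p * (1 - p) / row_sums[i, 0])
                assert abs(P_hat[i, j] - p) < 3 * se + 1e-12


def brute_force_best_modularity(g):
    """Exhaustive modularity maximization over all partitions (≤ 10 nodes)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, *rest = seq
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1:]
            yield part + [{head}]

    best = -np.inf
    for part in partitions(nodes):
        m = nx.community.modularity(g, part, weight="weight")
        best = max(best, m)
    return best


class TestCommunities:
    def two_cliques(self):
        g1 = nx.complete_graph(5)
        g2 = nx.relabel_nodes(nx.complete_graph(5), {i: i + 5 for i in range(5)})
        g = nx.compose(g1, g2)
        g.add_edge(4, 5)
        counts = nx.to_numpy_array(g, nodelist=range(10))
        return TransitionNetwork(list(range(10)), counts)

    def test_two_cliques_match_exhaustive_optimum(self):
        net = self.two_cliques()
        labels = detect_communities(net, seed=0)
        assert len(set(labels.values())) == 2
        assert len({labels[i] for i in range(5)}) == 1
        assert len({labels[i] for i in range(5, 10)}) == 1
        g = net.to_graph(symmetrized=True)
        achieved = nx.community.modularity(
            g, [{n for n in g if labels[n] == c} for c in set(labels.values())], weight="weight"
        )
        assert achieved == pytest.approx(brute_force_best_modularity(g), abs=1e-12)

    def test_single_state_with_self_loops(self):
        net = build_transition_matrix(series_from_states([0] * 5))
        labels = detect_communities(net)
        assert labels == {0: 0}

    def test_disconnected_components_not_merged(self):
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = 3
        counts[2, 3] = counts[3, 2] = 3
        net = TransitionNetwork(list(range(4)), counts)
        labels = detect_communities(net, seed=0)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_deterministic_given_seed(self):
        net = self.two_cliques()
        a = detect_communities(net, seed=42)
        b = detect_communities(net, seed=42)
        assert a == b

    def test_state_relabeling_leaves_modularity_invariant(self):
        net = self.two_cliques()
        labels = detect_communities(net, seed=0)
        g = net.to_graph(symmetrized=True)
        mod = nx.community.modularity(
            g, [{n for n in g if labels[n] == c} for c in set(labels.values())], weight="weight"
        )
        perm = np.random.default_rng(0).permutation(10)
        counts_p = net.counts[np.ix_(perm, perm)]
        net_p = TransitionNetwork(list(range(10)), counts_p)
        labels_p = detect_communities(net_p, seed=0)
        g_p = net_p.to_graph(symmetrized=True)
        mod_p = nx.community.modularity(
            g_p,
            [{n for n in g_p if labels_p[n] == c} for c in set(labels_p.values())],
            weight="weight",
        )
        assert mod == pytest.approx(mod_p, abs=1e-12)


class TestSummaries:
    def test_mean_of_raw_descriptors(self):
        raw = np.array([[0.0, 0.0, 20.0], [0.0, 0.0, 23.0]])
        series = series_from_states([0, 0], raw=raw)
        net = build_transition_matrix(series)
        detect_communities(net)
        df = summarize_communities(net, series)
        assert df.loc[0, "dNC"] == pytest.approx(21.5)
        assert df.loc[0, "population_fraction"] == 1.0

    def test_population_fractions_sum_to_one(self):
        states = np.array([0, 1, 2, 1, 0, 0, 2, 2, 2, 1])
        series = series_from_states(states)
        net = build_transition_matrix(series)
        detect_communities(net, seed=0)
        df = summarize_communities(net, series)
        assert df["population_fraction"].sum() == pytest.approx(1.0)


class TestNodeSizes:
    @pytest.mark.parametrize(
        "populations,expected",
        [
            ([2, 11], [1.0, 10.0]),
            ([4, 4, 4], [5.5, 5.5, 5.5]),
            ([0, 5, 10], [1.0, 5.5, 10.0]),
        ],
    )
    def test_linear_scale(self, populations, expected):
        assert scale_node_sizes(populations) == pytest.approx(expected)


class TestExport:
    @pytest.mark.parametrize("fmt,reader", [
        ("gexf", nx.read_gexf),
        ("graphml", nx.read_graphml),
    ])
    def test_round_trip(self, tmp_path, fmt, reader):
        states = [0, 0, 1, 1, 2, 0, 1, 2, 2, 0]
        series = series_from_states(states)
        net = build_transition_matrix(series)
        detect_communities(net, seed=0)
        summarize_communities(net, series)
        path = tmp_path / f"net.{fmt}"
        export_network(net, path, fmt)
        g = reader(path)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == net.to_graph().number_of_edges()
        node = g.nodes["0"] if "0" in g.nodes else g.nodes[0]
        for attr in ("population", "size", "community", "Nalpha", "Nbeta", "dNC"):
            assert attr in node
        assert 1.0 <= node["size"] <= 10.0

    def test_graphml_preserves_float_precision(self, tmp_path):
        series = series_from_states([0, 1, 0, 1], raw=np.array(
            [[0, 0, 20.123456789012], [0, 0, 30.5], [0, 0, 20.123456789012], [0, 0, 30.5]]))
        net = build_transition_matrix(series)
        detect_communities(net, seed=0)
        summarize_communities(net, series)
        path = tmp_path / "net.graphml"
        export_network(net, path, "graphml")
        g = nx.read_graphml(path)
        key = "0" if "0" in g.nodes else 0
        assert g.nodes[key]["dNC"] == pytest.approx(20.123456789012, abs=1e-12)

    def test_single_node_no_edge_network(self, tmp_path):
        series = series_from_states([0, 0])
        net = build_transition_matrix(series)
        path = tmp_path / "deg.gexf"
        export_network(net, path, "gexf")
        g = nx.read_gexf(path)
        assert g.number_of_nodes() == 1

    def test_csv_edgelist(self, tmp_path):
        series = series_from_states([0, 1, 0])
        net = build_transition_matrix(series)
        detect_communities(net, seed=0)
        path = tmp_path / "edges.csv"
        export_network(net, path, "csv_edgelist")
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "source,target,count"
        assert len(lines) == 1 + net.to_graph().number_of_edges()
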