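"""Transition networks over discrete conformational states.

Nodes are the dense state ids produced by the descriptor projection,
edges count observed frame-to-frame transitions at a fixed lag (never
across segment boundaries).  A node's population is its diagonal
self-transition count — a state with many self-transitions is kinetically
stable, i.e. sits in a deeper free-energy basin.  Communities are found
by modularity maximization on the symmetrized count graph (self-loops
excluded) and are interpreted as basins of the free-energy landscape;
per-community averages of the raw descriptor values summarize what the
basin looks like structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .descriptors import DescriptorStateSeries

__all__ = [
    "TransitionNetwork",
    "build_transition_matrix",
    "detect_communities",
    "summarize_communities",
    "scale_node_sizes",
    "export_network",
]


@dataclass
class TransitionNetwork:
    states: list[int]  # dense state ids (node set)
    counts: np.ndarray  # (n_states, n_states) directed transition counts
    lag: int = 1
    communities: dict[int, int] | None = None  # state -> community label
    community_summary: pd.DataFrame | None = None
    series: DescriptorStateSeries | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        n = len(self.states)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the state set")
        if np.any(self.counts < 0):
            raise ValueError("transition counts must be non-negative")

    @property
    def populations(self) -> np.ndarray:
        """Diagonal self-transition counts (the node 'population')."""
        return np.diag(self.counts).astype(float)

    def to_graph(self, *, symmetrized: bool = False, include_self_loops: bool = True):
        """Directed count graph, or the symmetrized undirected graph used
        for community detection (weight(i,j) = count(i,j) + count(j,i),
        self-loops dropped)."""
        if symmetrized:
            g = nx.Graph()
            g.add_nodes_from(self.states)
            sym = self.counts + self.counts.T
            for i, si in enumerate(self.states):
                for j in range(i + 1, len(self.states)):
                    if sym[i, j] > 0:
                        g.add_edge(si, self.states[j], weight=float(sym[i, j]))
            return g
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for i, si in enumerate(self.states):
            for j, sj in enumerate(self.states):
                if self.counts[i, j] > 0 and (include_self_loops or i != j):
                    g.add_edge(si, sj, count=int(self.counts[i, j]))
        return g


def build_transition_matrix(
    series: DescriptorStateSeries,
    segments: list[tuple[int, int]] | None = None,
    lag: int = 1,
) -> TransitionNetwork:
    """Count lag-``lag`` transitions within each independent segment.

    Entry (i, j) is the number of ordered frame pairs (t, t+lag) inside
    one segment with S(t) = i and S(t+lag) = j; pairs spanning a segment
    boundary are never counted, so the total count is
    Σ_segments (len − lag).
    """
    if lag < 1:
        raise ValueError("lag must be ≥ 1")
    s = series.states
    if segments is None:
        segments = [(0, len(s))]
    for start, end in segments:
        if end - start <= lag:
            raise ValueError(f"segment ({start},{end}) is not longer than lag {lag}")
    n = series.n_states
    counts = np.zeros((n, n), dtype=np.int64)
    for start, end in segments:
        seg = s[start:end]
        np.add.at(counts, (seg[:-lag], seg[lag:]), 1)
    return TransitionNetwork(list(range(n)), counts, lag=lag, series=series)


def detect_communities(
    net: TransitionNetwork, resolution: float = 1.0, seed: int = 0
) -> dict[int, int]:
    """Modularity communities on the symmetrized graph, deterministic per seed.

    Louvain-style modularity maximization (networkx) on the undirected
    weighted graph with self-loops removed; isolated nodes become
    singleton communities.  Labels are dense integers ordered by the
    smallest state id in each community.
    """
    if len(net.states) == 0:
        raise ValueError("empty network")
    g = net.to_graph(symmetrized=True)
    if g.number_of_edges() == 0:
        parts = [{s} for s in net.states]
    else:
        parts = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed
        )
    parts = sorted((sorted(p) for p in parts), key=lambda p: p[0])
    labels = {state: ci for ci, members in enumerate(parts) for state in members}
    net.communities = labels
    return labels


def summarize_communities(
    net: TransitionNetwork, series: DescriptorStateSeries | None = None
) -> pd.DataFrame:
    """Per-community averages of the raw descriptor values and population fractions.

    Averages run over all *frames* whose state belongs to the community
    (population-weighted by construction); fractions sum to 1.
    """
    series = series or net.series
    if series is None:
        raise ValueError("a descriptor series is required for community summaries")
    if net.communities is None:
        detect_communities(net)
    frame_comm = np.array([net.communities[s] for s in series.states])
    rows = []
    total = len(series.states)
    for label in sorted(set(net.communities.values())):
        mask = frame_comm == label
        row = {"community": label, "n_states": sum(1 for v in net.communities.values() if v == label)}
        if mask.any():
            means = series.raw[mask].mean(axis=0)
        else:  # states never visited cannot occur with dense ids, but stay safe
            means = np.full(series.raw.shape[1], np.nan)
        for name, value in zip(series.spec.names, means):
            row[name] = float(value)
        row["population_fraction"] = float(mask.sum()) / total
        rows.append(row)
    df = pd.DataFrame(rows).set_index("community")
    net.community_summary = df
    return df


def scale_node_sizes(populations) -> np.ndarray:
    """Map node populations linearly onto display sizes in [1, 10].

    size = 1 + 9·(p − pmin)/(pmax − pmin); when all populations are equal
    every node gets the midpoint 5.5.
    """
    p = np.asarray(populations, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one node")
    lo, hi = p.min(), p.max()
    if hi == lo:
        return np.full(p.shape, 5.5)
    return 1.0 + 9.0 * (p - lo) / (hi - lo)


def export_network(net: TransitionNetwork, path, format: str = "gexf") -> None:
    """Write the directed network for Gephi or any standard graph reader.

    Node attributes: per-state descriptor means (Nalpha, Nbeta, dNC),
    population (self-transition count), display size in [1, 10],
    community label and the community-average descriptors; edge
    attribute: transition count.  Formats: gexf, graphml, csv_edgelist.
    """
    if net.communities is None:
        detect_communities(net)
    summary = net.community_summary
    if summary is None and net.series is not None:
        summary = summarize_communities(net)
    g = net.to_graph(include_self_loops=True)
    sizes = scale_node_sizes(net.populations)
    state_pos = {s: i for i, s in enumerate(net.states)}

    state_means = None
    if net.series is not None:
        state_means = {}
        for s in net.states:
            mask = net.series.states == s
            state_means[s] = net.series.raw[mask].mean(axis=0) if mask.any() else None

    for s in g.nodes:
        i = state_pos[s]
        g.nodes[s]["population"] = float(net.populations[i])
        g.nodes[s]["size"] = float(sizes[i])
        g.nodes[s]["community"] = int(net.communities[s])
        if state_means is not None and state_means[s] is not None:
            names = net.series.spec.names
            for name, v in zip(names, state_means[s]):
                g.nodes[s][name] = float(v)
            if summary is not None:
                comm = net.communities[s]
                for name in names:
                    g.nodes[s][f"community_{name}"] = float(summary.loc[comm, name])

    format = format.lower()
    if format == "gexf":
        nx.write_gexf(g, path)
    elif format == "graphml":
        nx.write_graphml(g, path)
    elif format == "csv_edgelist":
        with open(path, "w") as fh:
            fh.write("source,target,count\n")
            for u, v, data in g.edges(data=True):
                fh.write(f"{u},{v},{data['count']}\n")
    else:
        raise ValueError(f"unsupported network format: {format!r}")
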