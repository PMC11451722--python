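"""Recurrence networks: the recurrence matrix as a graph adjacency.

Each embedded state is a node; two states are linked when they are
epsilon-close, i.e. the (self-loop-free) recurrence matrix is the adjacency
matrix of an undirected graph. Network statistics of this graph probe the
geometry of the attractor: clustering reflects the local dimensionality of
the invariant set, path lengths and efficiency its global diameter
structure, betweenness the transition bottlenecks between attractor regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .recurrence import RecurrenceMatrix


@dataclass
class RecurrenceGraph:
    adjacency: np.ndarray  # (n, n) uint8, symmetric, zero diagonal
    epsilon: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


def rn_adjacency(R: RecurrenceMatrix, zero_theiler: bool = True) -> RecurrenceGraph:
    """Adjacency matrix: the recurrence matrix with the self-loop diagonal
    (and, by default, the whole Theiler band) zeroed."""
    adj = R.matrix.copy()
    n = adj.shape[0]
    width = R.theiler if zero_theiler else 0
    for off in range(-width, width + 1):
        idx = np.arange(max(0, -off), min(n, n - off))
        adj[idx + off, idx] = 0
    np.fill_diagonal(adj, 0)
    return RecurrenceGraph(adjacency=adj, epsilon=R.epsilon)


#: Measure names of the network block, in reporting order.
NETWORK_MEASURES = ["edge_density", "transitivity", "avg_clustering",
                    "avg_path_length", "global_efficiency", "mean_betweenness"]

_BETWEENNESS_EXACT_MAX = 2000


def rn_measures(G: RecurrenceGraph, seed: int = 0) -> dict[str, float]:
    """Global statistics of the recurrence network.

    Path-based measures on a disconnected graph are computed on the largest
    connected component and flagged via the ``connected`` entry. Betweenness
    on graphs above 2000 nodes is estimated from a seeded uniform node
    subsample (exact below that size).
    """
    if G.n_nodes < 3:
        raise ValueError("need at least 3 nodes for network measures")
    g = G.to_networkx()
    n = g.number_of_nodes()
    components = list(nx.connected_components(g))
    connected = len(components) == 1
    giant = g.subgraph(max(components, key=len))
    if giant.number_of_nodes() >= 2:
        apl = nx.average_shortest_path_length(giant)
    else:
        apl = 0.0
    k = None if n <= _BETWEENNESS_EXACT_MAX else _BETWEENNESS_EXACT_MAX
    bc = nx.betweenness_centrality(g, k=k, seed=seed)
    return {
        "edge_density": nx.density(g),
        "transitivity": nx.transitivity(g),
        "avg_clustering": nx.average_clustering(g),
        "avg_path_length": float(apl),
        "global_efficiency": nx.global_efficiency(g),
        "mean_betweenness": float(np.mean(list(bc.values()))),
        "connected": float(connected),
    }
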