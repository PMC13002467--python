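"""Weighted-graph topology statistics on latent connectivity networks.

The latent network of a participant is the outer product of their
posterior-mean latent vector with the diagonal zeroed; centralities follow
the association-strength convention distance = 1/weight.  Graphs with
negative edges are uniformly shifted by the magnitude of the most negative
edge before path-based centralities; edges shifted to exactly zero are
removed (a zero weight is not a positive weight, and an epsilon stand-in
would dominate shortest paths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class WeightedGraph:
    weights: np.ndarray                 # (V, V) symmetric, zero diagonal
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        v = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape != (v, v):
            raise ValueError("weights must be square")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(self.weights) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if not self.labels:
            self.labels = [str(u + 1) for u in range(v)]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def latent_network(
    Z_mean: np.ndarray, participant: int | str = "average",
    labels: list[str] | None = None,
) -> WeightedGraph:
    """Outer-product network z z' of one participant's (or the participant-
    averaged) posterior-mean latent vector, diagonal zeroed."""
    Z_mean = np.atleast_2d(np.asarray(Z_mean, dtype=float))
    if participant == "average":
        z = Z_mean.mean(axis=0)
    else:
        idx = int(participant)
        if not 0 <= idx < Z_mean.shape[0]:
            raise IndexError(
                f"unknown participant {participant} (N={Z_mean.shape[0]})"
            )
        z = Z_mean[idx]
    w = np.outer(z, z)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(weights=w, labels=labels or [])


def node_strength(g: WeightedGraph) -> np.ndarray:
    """Sum of edge weights at each node (diagonal excluded)."""
    return g.weights.sum(axis=1)


def _positive_shift(weights: np.ndarray) -> np.ndarray:
    """Add |most negative edge| to all off-diagonal edges if any is negative;
    edges landing at exactly zero are treated as absent (set to 0 here and
    skipped when building the graph)."""
    v = weights.shape[0]
    iu = np.triu_indices(v, k=1)
    vals = weights[iu]
    if vals.size and vals.min() < 0:
        shifted = vals + abs(vals.min())
    else:
        shifted = vals
    out = np.zeros_like(weights)
    out[iu] = shifted
    out += out.T
    return out


def _distance_graph(weights: np.ndarray) -> nx.Graph:
    v = weights.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(v))
    iu = np.triu_indices(v, k=1)
    for u, w_ix in zip(*iu):
        wt = weights[u, w_ix]
        if wt > 0:
            graph.add_edge(int(u), int(w_ix), distance=1.0 / wt)
    return graph


def shifted_closeness(g: WeightedGraph) -> np.ndarray:
    """Closeness 1 / sum of shortest-path distances to reachable nodes,
    after the positive shift; nodes reaching no one get 0."""
    if g.n_nodes < 2:
        raise ValueError("closeness needs at least 2 nodes")
    graph = _distance_graph(_positive_shift(g.weights))
    out = np.zeros(g.n_nodes)
    for u in range(g.n_nodes):
        lengths = nx.single_source_dijkstra_path_length(
            graph, u, weight="distance"
        )
        total = sum(d for node, d in lengths.items() if node != u)
        out[u] = 1.0 / total if total > 0 else 0.0
    return out


def betweenness(g: WeightedGraph) -> np.ndarray:
    """Shortest-path betweenness (Brandes, unnormalized, fractional ties)
    on the positively shifted graph with distance = 1/weight."""
    if g.n_nodes < 2:
        raise ValueError("betweenness needs at least 2 nodes")
    graph = _distance_graph(_positive_shift(g.weights))
    bc = nx.betweenness_centrality(graph, weight="distance", normalized=False)
    return np.array([bc[u] for u in range(g.n_nodes)])


def moment_summary(values: np.ndarray) -> tuple[float, float]:
    """Sample skewness and excess kurtosis (bias-uncorrected moments)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise ValueError("need at least 4 values")
    centered = values - values.mean()
    m2 = float((centered**2).mean())
    if m2 == 0.0:
        return float("nan"), float("nan")
    skew = float((centered**3).mean()) / m2**1.5
    kurt = float((centered**4).mean()) / m2**2 - 3.0
    return skew, kurt
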