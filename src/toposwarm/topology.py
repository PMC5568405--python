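"""Directed K-nearest-neighbour interaction graph.

Information flows from a perceived neighbour to its perceiver: if agent
``i`` counts ``j`` among its ``K`` nearest, the graph carries the edge
``j -> i``.  Under this convention every agent's in-degree equals exactly
``min(K, N-1)`` at every step — perception capacity is fixed by
construction — while the out-degree of an agent counts how many others
perceive it, i.e. its influence, and is free to vary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .model_core import SwarmState

__all__ = [
    "InteractionGraph",
    "k_nearest_neighbors",
    "neighbor_table",
    "build_graph",
    "out_degree_distribution",
    "write_edgelist",
    "write_graphml",
]


@dataclass(frozen=True)
class InteractionGraph:
    """Who-perceives-whom digraph at one time step.

    ``edges`` is an (E, 2) integer array of ordered pairs
    ``(source=perceived neighbour, target=perceiver)``; ``E = N*min(K, N-1)``.
    """

    n_nodes: int
    K: int
    edges: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "edges", edges)
        if edges.size and (edges[:, 0] == edges[:, 1]).any():
            raise InvalidInputError("interaction graph must not contain self-loops")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 1], minlength=self.n_nodes)

    @property
    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.n_nodes)

    def adjacency(self):
        """Sparse CSR adjacency matrix (source row, target column)."""
        from scipy.sparse import csr_matrix

        return csr_matrix(
            (np.ones(self.n_edges), (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_nodes, self.n_nodes),
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g


def _distance_matrix(state: SwarmState) -> np.ndarray:
    diff = state.positions[:, None, :] - state.positions[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def neighbor_table(state: SwarmState, K: int) -> np.ndarray:
    """(N, K) table of each agent's K nearest neighbours.

    Row ``i`` is sorted by (distance, agent index): exact distance ties are
    broken by ascending index so graphs, and hence trajectories, are fully
    deterministic.
    """
    n = state.n_agents
    if not (0 <= K <= n - 1):
        raise InvalidInputError(f"K must satisfy 0 <= K <= N-1 (N={n}), got {K}")
    if K == 0:
        return np.empty((n, 0), dtype=np.int64)
    dist = _distance_matrix(state)
    np.fill_diagonal(dist, np.inf)
    # stable sort on distance keeps ascending index order among exact ties
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :K].astype(np.int64)

def k_nearest_neighbors(state: SwarmState, i: int, K: int) -> list[int]:
    """The K agents nearest to agent ``i`` (rank-based, no distance cutoff).

    Result is ordered by (distance, index); ties broken by ascending index.
    """
    n = state.n_agents
    if not (0 <= i < n):
        raise InvalidInputError(f"agent index {i} out of range for N={n}")
    return neighbor_table(state, K)[i].tolist()


def build_graph(state: SwarmState, K: int, step: int | None = None) -> InteractionGraph:
    """Build the directed interaction graph: edge ``j -> i`` iff ``i`` perceives ``j``."""
    table = neighbor_table(state, K)
    n = state.n_agents
    targets = np.repeat(np.arange(n, dtype=np.int64), table.shape[1])
    edges = np.column_stack([table.ravel(), targets])
    return InteractionGraph(
        n_nodes=n, K=K, edges=edges, step=state.step if step is None else step
    )


def out_degree_distribution(graph: InteractionGraph) -> np.ndarray:
    """Histogram over out-degree values, indexed 0..N-1; counts sum to N."""
    return np.bincount(graph.out_degrees, minlength=graph.n_nodes)


def write_edgelist(graph: InteractionGraph, path) -> None:
    """Whitespace-delimited ``source target`` lines, 0-based."""
    np.savetxt(path, graph.edges, fmt="%d")


def write_graphml(graph: InteractionGraph, path) -> None:
    """GraphML snapshot with node attribute agent_id and graph attrs step, N, K."""
    g = graph.to_networkx()
    for node in g.nodes:
        g.nodes[node]["agent_id"] = int(node)
    g.graph.update(step=int(graph.step), N=int(graph.n_nodes), K=int(graph.K))
    import networkx as nx

    nx.write_graphml(g, path)
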