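"""Network properties of the interaction graph and their time series.

Four metrics summarise the who-perceives-whom digraph:

* density ``D = E / (N*(N-1))`` — for a K-nearest graph this is exactly
  ``K/(N-1)`` and constant over the whole run;
* network entropy — Shannon entropy (nats) of the out-degree distribution;
  zero iff every agent influences the same number of others, as in the
  complete graph at ``K = N-1`` (a k-regular digraph);
* average geodesic distance — mean directed shortest-path length in hops
  over the ordered pairs that are reachable; after the group splits,
  cross-subgroup pairs become unreachable and are excluded (their geodesic
  distance is infinite), which is reported via the reachable-pair fraction;
* average clustering coefficient — mean local clustering on the undirected
  projection (an undirected edge wherever either direction exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError
from .model_core import Trajectory
from .topology import InteractionGraph, build_graph

__all__ = [
    "NetworkMetrics",
    "density",
    "network_entropy",
    "average_geodesic",
    "average_clustering",
    "n_weak_components",
    "compute_metrics",
    "metrics_timeseries",
    "write_metrics_csv",
]


@dataclass(frozen=True)
class NetworkMetrics:
    """All graph metrics evaluated at one step."""

    step: int
    density: float
    entropy: float
    avg_geodesic: float
    avg_clustering: float
    reachable_pair_fraction: float
    n_components: int


def density(graph: InteractionGraph) -> float:
    """Edge count over ``N*(N-1)``; equals ``K/(N-1)`` for any K-nearest graph."""
    n = graph.n_nodes
    if n < 2:
        raise UndefinedMetricError("density undefined for N < 2")
    return graph.n_edges / (n * (n - 1))


def network_entropy(graph: InteractionGraph) -> float:
    """Shannon entropy (natural log) of the out-degree distribution.

    Zero exactly when all out-degrees are equal; the in-degree distribution
    is degenerate by construction, so the out-degrees carry all the
    heterogeneity of the network.
    """
    counts = np.bincount(graph.out_degrees)
    p = counts[counts > 0] / graph.n_nodes
    return float(-(p * np.log(p)).sum()) + 0.0  # avoid IEEE -0.0


def average_geodesic(graph: InteractionGraph) -> tuple[float, float]:
    """Mean directed shortest-path length over reachable ordered pairs.

    Returns ``(avg_geodesic, reachable_pair_fraction)``.  Unreachable pairs
    (infinite geodesic distance) are excluded from the mean; the fraction
    of ordered pairs that remain reachable is returned alongside.
    """
    from scipy.sparse.csgraph import shortest_path

    n = graph.n_nodes
    if n < 2:
        raise UndefinedMetricError("average geodesic distance undefined for N < 2")
    sp = shortest_path(graph.adjacency(), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(sp) & off
    n_pairs = n * (n - 1)
    if not finite.any():
        raise UndefinedMetricError("no reachable ordered pair in the graph")
    return float(sp[finite].mean()), float(finite.sum() / n_pairs)


def average_clustering(graph: InteractionGraph) -> float:
    """Mean local clustering coefficient on the undirected projection."""
    import networkx as nx

    if graph.n_nodes < 3:
        raise UndefinedMetricError("clustering undefined for N < 3")
    return float(nx.average_clustering(graph.to_networkx().to_undirected()))


def n_weak_components(graph: InteractionGraph) -> int:
    from scipy.sparse.csgraph import connected_components

    ncomp, _ = connected_components(
        graph.adjacency(), directed=True, connection="weak"
    )
    return int(ncomp)


def compute_metrics(graph: InteractionGraph) -> NetworkMetrics:
    g, frac = average_geodesic(graph)
    return NetworkMetrics(
        step=graph.step,
        density=density(graph),
        entropy=network_entropy(graph),
        avg_geodesic=g,
        avg_clustering=average_clustering(graph),
        reachable_pair_fraction=frac,
        n_components=n_weak_components(graph),
    )


def metrics_timeseries(trajectory: Trajectory, stride: int = 1):
    """Evaluate all metrics every ``stride`` stored states.

    ``stride`` counts stored states (which may themselves be thinned), and
    the final state is always included.  Returns a pandas DataFrame with
    one row per evaluated step.
    """
    import pandas as pd

    if stride < 1:
        raise UndefinedMetricError("stride must be >= 1")
    idx = list(range(0, len(trajectory.states), stride))
    if idx[-1] != len(trajectory.states) - 1:
        idx.append(len(trajectory.states) - 1)
    rows = []
    for s in idx:
        graph = build_graph(trajectory.states[s], trajectory.params.K)
        rows.append(vars(compute_metrics(graph)))
    return pd.DataFrame(rows)


def write_metrics_csv(frame, path) -> None:
    frame.to_csv(path, index=False)
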