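"""Order parameters, motion-type classification and fission detection.

Two dimensionless order parameters summarise a run over an analysis
window (by default the last quarter, to skip transients):

* straightness ``S`` — chord-over-arc ratio of the group centroid path;
  1 for straight translation, 0 for a closed orbit;
* helicity ``H`` — time-averaged normalised group angular momentum about
  the instantaneous centroid, ``|sum_i r_i x v_i| / sum_i |r_i||v_i|``;
  1 for rigid rotation, 0 for pure translation.

Eight motion types are distinguished.  Types 1-6 order by decreasing
straightness (and broadly increasing helicity): from straight translation
(1) through helical/spiral travel (3, 4) to closed torus-like milling
(5, 6).  Type 7 is rapid aggregation into a fully static equilibrium;
type 8 is motion that never organises.  Fission — the group splitting into
subgroups whose interaction digraph disconnects — pre-empts all of them.
The cut points between types 1-6 are configuration, not constants: the
model pins only the qualitative ordering of S and H across types, so any
specific thresholds are a reporting choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .model_core import ModelParams, Trajectory
from .topology import InteractionGraph, build_graph

__all__ = [
    "OrderParameters",
    "BehaviorReport",
    "ClassifierConfig",
    "straightness",
    "helicity",
    "order_parameters",
    "detect_fission",
    "classify_motion",
    "analyze_run",
    "write_behavior_json",
]


@dataclass(frozen=True)
class OrderParameters:
    """Straightness and helicity over one analysis window of stored states."""

    straightness: float
    helicity: float
    window: tuple[int, int]
    stationary: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.window[0] < self.window[1]):
            raise InvalidInputError(f"empty or inverted window {self.window}")


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the motion-type cascade.

    ``s_bounds`` are the descending straightness cut points separating
    types 1|2, 2|3, 3|4, 4|5 and 5|6.  ``window_frac`` is the trailing
    fraction of stored states analysed.  ``settle_tol_factor`` (times
    ``d_e``) bounds how much the mean nearest-neighbour distance may drift
    over the window before the run counts as unsettled (type 8 candidate).
    ``static_tol_factor`` (times ``stability_tol * d_e``, per step) bounds
    the final per-agent displacement below which a stationary run counts
    as a fully static aggregate (type 7).  ``fission_window`` is the number
    of consecutive graph snapshots the digraph must stay disconnected.
    """

    s_bounds: tuple[float, ...] = (0.9, 0.7, 0.45, 0.2, 0.05)
    window_frac: float = 0.25
    settle_tol_factor: float = 0.05
    static_tol_factor: float = 1.0
    fission_window: int = 50


@dataclass
class BehaviorReport:
    """Classification outcome for one run."""

    motion_type: int | str
    order: OrderParameters
    subgroups: list[list[int]]
    fission_step: int | None
    n_subgroups: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_subgroups = len(self.subgroups)
        members = sorted(i for g in self.subgroups for i in g)
        if members != list(range(len(members))):
            raise InvalidInputError("subgroups must partition the agent indices")
        if self.motion_type == "fission" and self.n_subgroups < 2:
            raise InvalidInputError("fission report requires at least 2 subgroups")

    def to_dict(self) -> dict:
        return {
            "motion_type": self.motion_type,
            "straightness": self.order.straightness,
            "helicity": self.order.helicity,
            "n_subgroups": self.n_subgroups,
            "fission_step": self.fission_step,
            "subgroups": self.subgroups,
        }


def _window_slice(n_states: int, window) -> tuple[int, int]:
    if window is None:
        lo = min(int(np.floor(0.75 * n_states)), n_states - 2)
        return max(lo, 0), n_states
    lo, hi = window
    if not (0 <= lo < hi <= n_states):
        raise InvalidInputError(f"window {window} outside trajectory of {n_states} states")
    return lo, hi


def straightness(trajectory: Trajectory, window=None) -> float:
    """Chord-over-arc ratio of the centroid path over the window.

    Returns 0.0 for a zero-length path (fully static group); a value of 1
    means the centroid moved on a straight line, values near 0 mean it
    closed on itself.  Invariant under translation, rotation and uniform
    rescaling of the trajectory.
    """
    lo, hi = _window_slice(len(trajectory.states), window)
    cent = trajectory.centroid_path[lo:hi]
    if len(cent) < 2:
        raise InvalidInputError("straightness needs at least 2 stored states")
    arc = np.linalg.norm(np.diff(cent, axis=0), axis=1).sum()
    if arc == 0.0:
        return 0.0
    return float(np.linalg.norm(cent[-1] - cent[0]) / arc)


def helicity(trajectory: Trajectory, window=None) -> float:
    """Normalised group angular momentum about the centroid, time-averaged.

    At each stored transition, ``|sum_i r_i x v_i| / sum_i |r_i| |v_i|``
    with ``r_i`` the position relative to the centroid and ``v_i`` the
    displacement to the next stored state (cross product: scalar in 2-D,
    vector norm in 3-D).  Steps with zero displacement are skipped; a run
    with no motion at all returns 0.0.
    """
    lo, hi = _window_slice(len(trajectory.states), window)
    if hi - lo < 2:
        raise InvalidInputError("helicity needs at least 2 stored states")
    vals = []
    for s in range(lo, hi - 1):
        p_now = trajectory.states[s].positions
        p_next = trajectory.states[s + 1].positions
        r = p_now - p_now.mean(axis=0)
        v = p_next - p_now
        den = float((np.linalg.norm(r, axis=1) * np.linalg.norm(v, axis=1)).sum())
        if den == 0.0:
            continue
        cross = np.cross(r, v)
        num = abs(cross.sum()) if cross.ndim == 1 else float(np.linalg.norm(cross.sum(axis=0)))
        vals.append(num / den)
    return float(np.mean(vals)) if vals else 0.0


def order_parameters(trajectory: Trajectory, window=None) -> OrderParameters:
    lo, hi = _window_slice(len(trajectory.states), window)
    s = straightness(trajectory, (lo, hi))
    h = helicity(trajectory, (lo, hi))
    arc = np.linalg.norm(np.diff(trajectory.centroid_path[lo:hi], axis=0), axis=1).sum()
    return OrderParameters(s, h, (lo, hi), stationary=(arc == 0.0))


def detect_fission(
    graph_series: Sequence[InteractionGraph],
    window: int = 50,
    final_persists: bool = False,
) -> tuple[int | None, list[list[int]]]:
    """Detect a sustained split of the interaction digraph.

    Returns ``(fission_step, subgroups)`` where ``subgroups`` are the
    weakly connected components of the final graph and ``fission_step`` is
    the step of the first snapshot opening a run of at least ``window``
    consecutive disconnected snapshots that persists to the end of the
    series.  ``final_persists=True`` marks a series whose last
    configuration is a stationary equilibrium: the terminal state then
    repeats forever, so a trailing disconnected run of any length counts
    as sustained.
    """
    from scipy.sparse.csgraph import connected_components

    if not len(graph_series):
        raise InvalidInputError("graph series is empty")
    labels_final = None
    run_start = None
    run_len = 0
    for graph in graph_series:
        ncomp, labels = connected_components(
            graph.adjacency(), directed=True, connection="weak"
        )
        if ncomp > 1:
            if run_len == 0:
                run_start = graph.step
            run_len += 1
        else:
            run_start, run_len = None, 0
        labels_final = labels
    sustained = run_len >= window or (final_persists and run_len >= 1)
    subgroups = [
        np.flatnonzero(labels_final == c).tolist()
        for c in range(int(labels_final.max()) + 1)
    ]
    if sustained and len(subgroups) > 1:
        return run_start, subgroups
    return None, subgroups


def _mean_nn_settled(trajectory: Trajectory, lo: int, hi: int, tol: float) -> bool:
    """Whether the mean nearest-neighbour distance drifts < tol over the window."""
    vals = []
    for s in range(lo, hi):
        p = trajectory.states[s].positions
        d = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        vals.append(d.min(axis=1).mean())
    return (max(vals) - min(vals)) < tol


def classify_motion(
    trajectory: Trajectory,
    graph_series: Sequence[InteractionGraph],
    params: ModelParams,
    config: ClassifierConfig | None = None,
) -> BehaviorReport:
    """Assign a motion type through the decision cascade.

    1. fission, if the digraph shows a sustained split;
    2. type 7, if the run reached stationarity in a fully static
       configuration (per-agent displacement at the end is numerically
       zero: the group aggregated and froze);
    3. type 8, if the run neither reached stationarity within ``t_max``
       nor settled its mean nearest-neighbour distance (never organised);
    4. otherwise types 1-6 from the straightness cut points, with the
       lowest-straightness band split 5|6 by helicity (6 is the more
       purely rotational torus).
    """
    cfg = config or ClassifierConfig()
    n_states = len(trajectory.states)
    lo = min(int(np.floor((1 - cfg.window_frac) * n_states)), n_states - 2)
    lo = max(lo, 0)
    order = order_parameters(trajectory, (lo, n_states))
    stationary = trajectory.stationary_at is not None

    fission_step, subgroups = detect_fission(
        graph_series, window=cfg.fission_window, final_persists=stationary
    )
    if fission_step is not None:
        return BehaviorReport("fission", order, subgroups, fission_step)

    if stationary:
        last, prev = trajectory.states[-1], trajectory.states[-2]
        span = max(last.step - prev.step, 1)
        disp = np.linalg.norm(last.positions - prev.positions, axis=1).max() / span
        if disp < cfg.static_tol_factor * params.stability_tol * params.d_e:
            return BehaviorReport(7, order, subgroups, None)
    else:
        settled = _mean_nn_settled(
            trajectory, lo, n_states, cfg.settle_tol_factor * params.d_e
        )
        if not settled:
            return BehaviorReport(8, order, subgroups, None)

    s, h = order.straightness, order.helicity
    for t, bound in enumerate(cfg.s_bounds, start=1):
        if s >= bound:
            return BehaviorReport(t, order, subgroups, None)
    # lowest band: near-closed orbits; split rotation-dominated torus (6)
    # from its weaker counterpart (5)
    return BehaviorReport(6 if h >= 0.5 else 5, order, subgroups, None)


def analyze_run(
    trajectory: Trajectory, config: ClassifierConfig | None = None
) -> BehaviorReport:
    """Build graph snapshots from the stored states and classify the run."""
    graphs = [build_graph(s, trajectory.params.K) for s in trajectory.states]
    return classify_motion(trajectory, graphs, trajectory.params, config)


def write_behavior_json(report: BehaviorReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
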