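"""Core agent-based model: pairwise forces, force aggregation, position update.

The model describes ``N`` identical agents in unbounded 2-D or 3-D space.
Each agent perceives its ``K`` nearest neighbours by rank (topological
interaction) and feels, from each perceived neighbour at distance ``x``, a
piecewise pairwise force:

* ``d_l < x < d_e`` — repulsion of magnitude ``k1*(1/x - 1/d_e)``, which
  diverges at contact and vanishes at the equilibrium spacing ``d_e``;
* ``d_e < x <= (d_e+d_h)/2`` — attraction ``k2*sin((x-d_e)*pi/(d_h-d_e))``,
  a sine ramp that peaks at the saturation threshold ``(d_e+d_h)/2``;
* ``x > (d_e+d_h)/2`` — saturated attraction of constant magnitude ``k3``,
  so arbitrarily distant neighbours still attract at full strength;
* elsewhere (including exactly ``d_e``) — no force.

The resultant force on agent ``i`` is the weighted sum over its neighbour
set, ``F_i = sum_j (a*A(x_ij) - b*R(x_ij)) * u_ij`` with ``u_ij`` the unit
vector from ``i`` toward ``j``, and positions follow first-order dynamics
``S_i(t+1) = S_i(t) + c*F_i(t)`` — there is no velocity state and no
velocity alignment.  Because neighbour sets are directed (``i`` may perceive
``j`` without ``j`` perceiving ``i``) the summed forces do not cancel
pairwise, which is what lets the group translate and rotate collectively.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "ModelParams",
    "SwarmState",
    "Trajectory",
    "PairForce",
    "pair_force",
    "attraction_magnitude",
    "repulsion_magnitude",
    "net_force_weight",
    "resultant_force",
    "step",
    "run",
    "write_positions_csv",
    "write_trajectory_csv",
    "write_trajectory_hdf5",
    "read_trajectory_hdf5",
]


@dataclass(frozen=True)
class ModelParams:
    """All scalar constants of the model plus run control.

    Parameters
    ----------
    N : int
        Number of agents (1-50 in the reference simulations).
    K : int
        Number of topology: how many nearest neighbours each agent
        perceives, regardless of how far away they are.  ``0 <= K <= N-1``.
    d_l, d_e, d_h : float
        Lower repulsion bound, equilibrium (expected) distance, and upper
        attraction bound, in the shared length unit of the positions.
    k1, k2, k3 : float
        Force coefficients of the repulsive, sine-attraction and saturated
        attraction branches.  When ``k3 != k2`` the pairwise force is
        discontinuous at the saturation threshold; a warning is emitted.
    a, b : float
        Weights of attraction and repulsion in the resultant force.
    c : float
        Displacement produced per unit resultant force (first-order
        dynamics; effectively a time step).
    dims : int
        Spatial dimensionality, 2 or 3.
    t_max : int
        Maximum number of update steps per run.
    stability_tol : float
        Relative threshold for stationarity: the run is stationary when no
        pairwise distance changes by more than ``stability_tol * d_e`` in
        one step.  Stationarity is defined on the relative configuration,
        so a rigidly translating or rotating group still counts as stable.
    stability_window : int
        Number of consecutive quiet steps required to declare stationarity.
    """

    N: int
    K: int
    d_l: float = 0.0
    d_e: float = 5.2
    d_h: float = 12.0
    k1: float = 1.0
    k2: float = 0.3
    k3: float = 0.3
    a: float = 0.08
    b: float = 0.2
    c: float = 1.0
    dims: int = 3
    t_max: int = 20000
    stability_tol: float = 1e-6
    stability_window: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.d_l < self.d_e < self.d_h):
            raise InvalidInputError(
                f"require 0 <= d_l < d_e < d_h, got ({self.d_l}, {self.d_e}, {self.d_h})"
            )
        if min(self.k1, self.k2, self.k3) <= 0 or min(self.a, self.b, self.c) <= 0:
            raise InvalidInputError("force coefficients k1,k2,k3 and weights a,b,c must be > 0")
        if self.N < 1:
            raise InvalidInputError(f"N must be >= 1, got {self.N}")
        if not (0 <= self.K <= self.N - 1):
            raise InvalidInputError(
                f"K must satisfy 0 <= K <= N-1 (N={self.N}), got K={self.K}"
            )
        if self.dims not in (2, 3):
            raise InvalidInputError(f"dims must be 2 or 3, got {self.dims}")
        if self.t_max < 1:
            raise InvalidInputError(f"t_max must be >= 1, got {self.t_max}")
        if self.stability_tol <= 0 or self.stability_window < 1:
            raise InvalidInputError("stability_tol must be > 0 and stability_window >= 1")
        if self.k3 != self.k2:
            import warnings

            warnings.warn(
                "k3 != k2 makes the pairwise force discontinuous at the "
                "saturation threshold (d_e+d_h)/2",
                stacklevel=3,
            )

    @property
    def saturation_threshold(self) -> float:
        """Distance ``(d_e+d_h)/2`` beyond which attraction is constant ``k3``."""
        return 0.5 * (self.d_e + self.d_h)

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class SwarmState:
    """Positions of all agents at one time step."""

    positions: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise InvalidInputError(
                f"positions must be an (N, 2|3) array, got shape {pos.shape}"
            )
        if not np.isfinite(pos).all():
            raise InvalidInputError("positions contain non-finite coordinates")
        if self.step < 0:
            raise InvalidInputError(f"step must be >= 0, got {self.step}")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def dims(self) -> int:
        return self.positions.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass
class Trajectory:
    """Ordered sequence of stored states from one simulation run.

    ``states`` may be thinned by ``store_stride`` (the final state is always
    stored); ``centroid_path`` has one row per stored state.
    ``stationary_at`` is the first step of the first sustained quiet window,
    or ``None`` if the run never became stationary within ``t_max``.
    """

    states: list[SwarmState]
    params: ModelParams
    centroid_path: np.ndarray = field(default=None)  # type: ignore[assignment]
    stationary_at: int | None = None
    store_stride: int = 1

    def __post_init__(self) -> None:
        if self.centroid_path is None:
            self.centroid_path = np.array([s.centroid for s in self.states])
        if len(self.centroid_path) != len(self.states):
            raise InvalidInputError("centroid_path length must equal number of states")

    @property
    def steps(self) -> np.ndarray:
        return np.array([s.step for s in self.states])

    @property
    def final_state(self) -> SwarmState:
        return self.states[-1]

    @property
    def n_steps(self) -> int:
        """Number of dynamics steps actually simulated."""
        return self.states[-1].step


class PairForce(NamedTuple):
    """Magnitude and branch of the pairwise interaction at one distance."""

    value: float
    branch: str


def pair_force(x: float, params: ModelParams) -> PairForce:
    """Evaluate the piecewise pairwise force at separation ``x``.

    Returns a nonnegative magnitude together with the branch label
    (``repulsive``, ``attractive_sin``, ``attractive_saturated`` or
    ``none``).  The sign convention lives in the resultant-force sum:
    attraction pulls a perceiver toward its neighbour, repulsion pushes it
    away.

    The force vanishes exactly at ``x = d_e`` (equilibrium) and for
    ``x <= d_l``; it is continuous at the saturation threshold whenever
    ``k3 == k2`` since the sine branch reaches ``k2`` there.
    """
    if not math.isfinite(x):
        raise InvalidInputError(f"distance must be finite, got {x}")
    if x < 0:
        raise InvalidInputError(f"distance must be >= 0, got {x}")
    mid = params.saturation_threshold
    if params.d_l < x < params.d_e:
        return PairForce(params.k1 * (1.0 / x - 1.0 / params.d_e), "repulsive")
    if params.d_e < x <= mid:
        value = params.k2 * math.sin((x - params.d_e) * math.pi / (params.d_h - params.d_e))
        return PairForce(value, "attractive_sin")
    if x > mid:
        return PairForce(params.k3, "attractive_saturated")
    return PairForce(0.0, "none")


def attraction_magnitude(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorised attractive magnitude A(x) (sine and saturated branches)."""
    x = np.asarray(x, dtype=float)
    mid = params.saturation_threshold
    out = np.zeros_like(x)
    ramp = (x > params.d_e) & (x <= mid)
    out[ramp] = params.k2 * np.sin((x[ramp] - params.d_e) * np.pi / (params.d_h - params.d_e))
    out[x > mid] = params.k3
    return out


def repulsion_magnitude(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorised repulsive magnitude R(x) (inverse-distance branch)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    rep = (x > params.d_l) & (x < params.d_e)
    out[rep] = params.k1 * (1.0 / x[rep] - 1.0 / params.d_e)
    return out


def net_force_weight(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Signed net weight ``a*A(x) - b*R(x)``; positive pulls toward the neighbour."""
    return params.a * attraction_magnitude(x, params) - params.b * repulsion_magnitude(x, params)


def resultant_force(
    state: SwarmState,
    neighbor_sets: Sequence[Sequence[int]],
    params: ModelParams,
) -> np.ndarray:
    """Resultant force vectors for all agents given explicit neighbour sets.

    ``F_i = sum_{j in neighbours(i)} (a*A(x_ij) - b*R(x_ij)) * u_ij`` with
    ``u_ij`` the unit vector from ``i`` toward ``j``, computed componentwise
    on every axis.  Raises :class:`DegenerateGeometryError` if any listed
    neighbour coincides with its perceiver.
    """
    pos = state.positions
    n, dims = pos.shape
    expected = min(params.K, n - 1)
    forces = np.zeros((n, dims))
    for i, neigh in enumerate(neighbor_sets):
        neigh = list(neigh)
        if len(neigh) != expected:
            raise InvalidInputError(
                f"agent {i}: expected {expected} neighbours, got {len(neigh)}"
            )
        if i in neigh:
            raise InvalidInputError(f"agent {i} lists itself as a neighbour")
        if not neigh:
            continue
        diff = pos[neigh] - pos[i]
        dist = np.linalg.norm(diff, axis=1)
        if np.any(dist == 0.0):
            j = neigh[int(np.argmin(dist))]
            raise DegenerateGeometryError(
                f"agents {i} and {j} coincide; unit vector undefined"
            )
        w = net_force_weight(dist, params)
        forces[i] = (w[:, None] * diff / dist[:, None]).sum(axis=0)
    return forces


def step(state: SwarmState, params: ModelParams, neighbor_table=None) -> SwarmState:
    """Advance the swarm one step (synchronous update).

    Neighbour sets are recomputed from the current positions, all forces
    are evaluated on the time-``t`` configuration, then all positions move
    at once: ``S(t+1) = S(t) + c*F(t)``.  Deterministic given the state.
    """
    from .topology import neighbor_table as _neighbor_table

    if params.K > state.n_agents - 1:
        raise InvalidInputError(
            f"K={params.K} exceeds N-1={state.n_agents - 1}; choose a smaller K"
        )
    if neighbor_table is None:
        neighbor_table = _neighbor_table(state, params.K)
    forces = resultant_force(state, neighbor_table, params)
    return SwarmState(state.positions + params.c * forces, step=state.step + 1)


def run(initial: SwarmState, params: ModelParams, store_stride: int = 1) -> Trajectory:
    """Iterate the dynamics until stationarity or ``t_max`` steps.

    The stationarity criterion is relative: the largest one-step change of
    any pairwise distance must stay below ``stability_tol * d_e`` for
    ``stability_window`` consecutive steps.  A group translating or
    rotating rigidly therefore still registers as stationary.  States are
    stored every ``store_stride`` steps plus the final state.
    """
    if initial.n_agents != params.N:
        raise InvalidInputError(
            f"initial state has {initial.n_agents} agents, params.N={params.N}"
        )
    if initial.dims != params.dims:
        raise InvalidInputError(
            f"initial state is {initial.dims}-D, params.dims={params.dims}"
        )
    if store_stride < 1:
        raise InvalidInputError("store_stride must be >= 1")
    if params.N == 1:
        # a lone agent feels no force: the run is stationary from the start
        states = [initial, SwarmState(initial.positions.copy(), step=1)]
        return Trajectory(states, params, stationary_at=0, store_stride=store_stride)

    from ._kernel import simulate

    stored, stored_steps, stat_at = simulate(
        np.ascontiguousarray(initial.positions, dtype=np.float64),
        params.K,
        params.d_l,
        params.d_e,
        params.d_h,
        params.k1,
        params.k2,
        params.k3,
        params.a,
        params.b,
        params.c,
        params.t_max,
        params.stability_tol * params.d_e,
        params.stability_window,
        store_stride,
    )
    base = initial.step
    states = [
        SwarmState(stored[s], step=base + int(stored_steps[s]))
        for s in range(stored.shape[0])
    ]
    return Trajectory(
        states,
        params,
        stationary_at=(None if stat_at < 0 else base + int(stat_at)),
        store_stride=store_stride,
    )


# ---------------------------------------------------------------------------
# artifact I/O


def write_positions_csv(state: SwarmState, path) -> None:
    """Write one state as a headered CSV (agent_id, x, y[, z])."""
    cols = ["x", "y", "z"][: state.dims]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["agent_id", *cols])
        for i, row in enumerate(state.positions):
            w.writerow([i, *(repr(float(v)) for v in row)])


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    """Write all stored states as long-format CSV (step, agent_id, x, y[, z])."""
    import pandas as pd

    dims = trajectory.states[0].dims
    cols = ["x", "y", "z"][:dims]
    frames = []
    for s in trajectory.states:
        df = pd.DataFrame(s.positions, columns=cols)
        df.insert(0, "agent_id", np.arange(s.n_agents))
        df.insert(0, "step", s.step)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trajectory_hdf5(trajectory: Trajectory, path) -> None:
    """Write stored states into a single HDF5 container.

    Layout: dataset ``positions`` of shape (n_stored, N, dims), dataset
    ``steps`` with the step index of each block, and the full parameter set
    as root attributes.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "positions", data=np.stack([s.positions for s in trajectory.states])
        )
        fh.create_dataset("steps", data=trajectory.steps)
        fh.attrs["stationary_at"] = (
            -1 if trajectory.stationary_at is None else trajectory.stationary_at
        )
        fh.attrs["store_stride"] = trajectory.store_stride
        for key, value in vars(trajectory.params).items():
            fh.attrs[f"param_{key}"] = value


def read_trajectory_hdf5(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory_hdf5`."""
    import h5py

    with h5py.File(path, "r") as fh:
        positions = fh["positions"][...]
        steps = fh["steps"][...]
        pkeys = {k[len("param_"):]: fh.attrs[k] for k in fh.attrs if k.startswith("param_")}
        for key in ("N", "K", "dims", "t_max", "stability_window"):
            pkeys[key] = int(pkeys[key])
        params = ModelParams(**pkeys)
        stat = int(fh.attrs["stationary_at"])
        stride = int(fh.attrs["store_stride"])
    states = [SwarmState(positions[i], step=int(steps[i])) for i in range(len(steps))]
    return Trajectory(
        states, params, stationary_at=(None if stat < 0 else stat), store_stride=stride
    )
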