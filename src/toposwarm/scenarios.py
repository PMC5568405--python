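"""Seeded generators for the initial-condition families used in experiments.

Three families are provided, mirroring the study setups:

* ``uniform_cloud`` — agents drawn uniformly in a cube whose side is scaled
  so the expected nearest-neighbour spacing matches ``spacing``.  The
  default spacing (8.6, the saturation threshold) puts the cloud in the
  loosely distributed regime between the equilibrium distance and the
  attraction bound, so aggregation dominates the early dynamics.
* ``isolated_individual`` — a cloud of N-1 agents plus one agent placed
  ``isolation_offset`` away from the cloud centroid, beyond the saturation
  threshold so it feels full constant attraction toward its perceived
  neighbours.
* ``preformed_subgroups`` — 2 or 3 already-aggregated clouds (within-cloud
  spacing near the equilibrium distance) with centroids a mutual
  ``separation`` apart, beyond the attraction bound.

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, InvalidInputError
from .model_core import SwarmState

__all__ = ["ScenarioSpec", "generate", "load_positions"]

_D_E = 5.2
_D_H = 12.0
_SATURATION = 0.5 * (_D_E + _D_H)

_KINDS = ("uniform_cloud", "isolated_individual", "preformed_subgroups")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one initial-condition family.

    ``spacing`` is the target mean nearest-neighbour distance; when left
    ``None`` it resolves to 8.6 for clouds and to the equilibrium distance
    5.2 inside preformed subgroups.
    """

    kind: str
    N: int
    dims: int = 3
    spacing: float | None = None
    n_subgroups: int = 2
    separation: float = 52.0
    isolation_offset: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidInputError(f"unknown scenario kind {self.kind!r}; one of {_KINDS}")
        if self.N < 1:
            raise InvalidInputError(f"N must be >= 1, got {self.N}")
        if self.dims not in (2, 3):
            raise InvalidInputError(f"dims must be 2 or 3, got {self.dims}")
        if self.spacing is not None and self.spacing <= 0:
            raise InvalidInputError(f"spacing must be > 0, got {self.spacing}")
        if self.kind == "preformed_subgroups":
            if self.n_subgroups not in (2, 3):
                raise InvalidInputError("preformed_subgroups supports 2 or 3 subgroups")
            if self.separation <= _D_H:
                raise InvalidInputError(
                    f"separation must exceed the attraction bound {_D_H}, got {self.separation}"
                )
            if self.N < 2 * self.n_subgroups:
                raise InvalidInputError("need at least 2 agents per subgroup")
        if self.kind == "isolated_individual":
            if self.isolation_offset <= _SATURATION:
                raise InvalidInputError(
                    f"isolation_offset must exceed the saturation threshold {_SATURATION}"
                )
            if self.N < 2:
                raise InvalidInputError("isolated_individual needs N >= 2")

    @property
    def resolved_spacing(self) -> float:
        if self.spacing is not None:
            return self.spacing
        return _D_E if self.kind == "preformed_subgroups" else _SATURATION


def _box_side(n: int, dims: int, spacing: float) -> float:
    # Poisson nearest-neighbour law: mean NN distance for intensity
    # lam = n / L^dims is Gamma(1+1/d) * (lam * V_d)**(-1/d)
    v_d = math.pi ** (dims / 2) / math.gamma(dims / 2 + 1)
    return spacing * (n * v_d) ** (1 / dims) / math.gamma(1 + 1 / dims)


def _cloud(rng: np.random.Generator, n: int, dims: int, spacing: float) -> np.ndarray:
    side = _box_side(n, dims, spacing)
    pos = rng.uniform(0.0, side, size=(n, dims))
    # coincident agents would make the force direction undefined; resample
    # the offending rows (deterministic: same rng stream)
    min_sep = 1e-6 * spacing
    for _ in range(100):
        if n == 1:
            break
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        bad = np.flatnonzero(d.min(axis=1) < min_sep)
        if not bad.size:
            break
        pos[bad] = rng.uniform(0.0, side, size=(bad.size, dims))
    return pos - pos.mean(axis=0)


def _subgroup_centers(spec: ScenarioSpec) -> np.ndarray:
    sep = spec.separation
    if spec.n_subgroups == 2:
        centers = np.array([[-sep / 2, 0.0], [sep / 2, 0.0]])
    else:  # equilateral triangle with side `separation`
        r = sep / math.sqrt(3)
        ang = math.pi / 2 + 2 * math.pi / 3 * np.arange(3)
        centers = r * np.column_stack([np.cos(ang), np.sin(ang)])
    if spec.dims == 3:
        centers = np.column_stack([centers, np.zeros(len(centers))])
    return centers


def generate(spec: ScenarioSpec) -> SwarmState:
    """Generate the initial state for ``spec``; deterministic given its seed."""
    rng = np.random.default_rng(spec.seed)
    spacing = spec.resolved_spacing
    if spec.kind == "uniform_cloud":
        if spec.N == 1:
            pos = np.zeros((1, spec.dims))
        else:
            pos = _cloud(rng, spec.N, spec.dims, spacing)
    elif spec.kind == "isolated_individual":
        cloud = _cloud(rng, spec.N - 1, spec.dims, spacing)
        direction = rng.normal(size=spec.dims)
        direction /= np.linalg.norm(direction)
        lone = cloud.mean(axis=0) + spec.isolation_offset * direction
        pos = np.vstack([cloud, lone])
    else:  # preformed_subgroups
        sizes = np.full(spec.n_subgroups, spec.N // spec.n_subgroups)
        sizes[: spec.N % spec.n_subgroups] += 1
        centers = _subgroup_centers(spec)
        parts = [
            _cloud(rng, int(size), spec.dims, spacing) + center
            for size, center in zip(sizes, centers)
        ]
        pos = np.vstack(parts)
    return SwarmState(pos, step=0)


def load_positions(path) -> SwarmState:
    """Load an initial state from a headered CSV (agent_id, x, y[, z]).

    Agent ids must be the contiguous range 0..N-1 (any row order);
    coordinates share the length unit of the model distances.  Malformed
    rows raise :class:`FormatError` naming the offending line.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        header = [h.strip().lower() for h in header]
        if header not in (["agent_id", "x", "y"], ["agent_id", "x", "y", "z"]):
            raise FormatError(
                f"{path}: line 1: header must be agent_id,x,y[,z], got {header}"
            )
        dims = len(header) - 1
        rows: dict[int, list[float]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != dims + 1:
                raise FormatError(
                    f"{path}: line {lineno}: expected {dims + 1} fields "
                    f"({dims}-D file), got {len(row)}"
                )
            try:
                agent = int(row[0])
                coords = [float(v) for v in row[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if not all(math.isfinite(v) for v in coords):
                raise FormatError(f"{path}: line {lineno}: non-finite coordinate")
            if agent in rows:
                raise FormatError(f"{path}: line {lineno}: duplicate agent_id {agent}")
            rows[agent] = coords
    if not rows:
        raise FormatError(f"{path}: no data rows")
    n = len(rows)
    if sorted(rows) != list(range(n)):
        raise FormatError(f"{path}: agent_id values must be the contiguous range 0..{n - 1}")
    return SwarmState(np.array([rows[i] for i in range(n)]), step=0)
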