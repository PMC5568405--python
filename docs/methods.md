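# Methods

## Model

`toposwarm` simulates `N` identical agents in unbounded 2-D or 3-D space.
Each agent perceives exactly its `K` nearest neighbours by rank — the
*number of topology* — with no perception radius: a neighbour attracts at
full strength no matter how far away it is.  From a perceived neighbour at
distance `x` an agent feels the piecewise pairwise force

```
f(x) = k1*(1/x - 1/d_e)                   d_l < x < d_e      (repulsion)
     = k2*sin((x - d_e)*pi/(d_h - d_e))   d_e < x <= (d_e+d_h)/2
     = k3                                 x > (d_e+d_h)/2    (saturated)
     = 0                                  otherwise
```

so repulsion diverges at contact (built-in collision avoidance), the force
vanishes at the equilibrium spacing `d_e`, attraction ramps sinusoidally
and saturates at the constant `k3` beyond the threshold `(d_e+d_h)/2`.
The resultant force on agent `i` sums over its neighbour set only,

```
F_i = sum_{j in nn_K(i)} (a*A(x_ij) - b*R(x_ij)) * u_ij
```

with `u_ij` the unit vector from `i` toward `j`, and positions follow the
first-order update `S_i(t+1) = S_i(t) + c*F_i(t)`.  There is no velocity
state and no velocity alignment.  Because the K-nearest relation is not
symmetric, pairwise forces do not cancel, and collective translation,
rotation and group fission all emerge from this asymmetry alone.

Default parameters: `d_l=0`, `d_e=5.2`, `d_h=12`, `k1=1`, `k2=0.3`,
`k3=0.3`, `a=0.08`, `b=0.2`, `c=1`, `t_max=20000` steps, 3-D space.
`k3 != k2` is permitted but makes `f` discontinuous at the saturation
threshold; the constructor warns rather than forbidding it, since nothing
in the dynamics breaks.  Updates are synchronous (all forces evaluated on
the time-`t` configuration), neighbour sets are recomputed every step, and
exact distance ties are broken by ascending agent index so every
trajectory is fully deterministic.  Exactly coincident agents raise an
error rather than producing infinities: under the continuous dynamics a
collision is a measure-zero event, so it can only arise from a pathological
hand-built input.

The compiled inner loop (`_kernel.py`, numba) selects neighbours with a
plain argsort, without the index tie-break; ties have measure zero along a
trajectory, and a property test pins the kernel to the pure-NumPy `step`
on random configurations.

## Stationarity

A run terminates early when the *relative configuration* freezes: the
largest one-step change over all pairwise distances stays below
`stability_tol * d_e` (default `1e-6 * d_e`) for `stability_window = 50`
consecutive steps.  Stationarity is deliberately defined on pairwise
distances, not displacements, because the stable collective motions
translate or rotate rigidly.  The defaults are small enough not to
truncate slowly-precessing spiral motions early; many spiral runs simply
use all `t_max` steps, which is fine — their order parameters are read
from the trailing window.

## Order parameters and the motion taxonomy

Two bounded, dimensionless order parameters are computed over the trailing
25% of stored states (transients in these dynamics can last thousands of
steps):

* **straightness** `S` — chord over arc of the group-centroid path; 1 for
  straight translation, 0 for a closed orbit.
* **helicity** `H` — time-averaged normalised group angular momentum about
  the instantaneous centroid, `|sum_i r_i x v_i| / sum_i |r_i||v_i|`; 1
  for rigid rotation, 0 for pure translation.  On discrete snapshots a
  rigid rotation by angle `w` per transition gives exactly `cos(w/2)`,
  which tends to 1 as the sampling gets finer.

Neither quantity has a canonical closed form in the emergent-behaviour
literature; these definitions were chosen because they are bounded,
similarity-invariant (translation, rotation, uniform rescaling) and map
the archetype motions to the expected corners: straight line `(1, 0)`,
torus `(~0, ~1)`.

Runs are classified by a cascade:

1. **fission** — the interaction digraph splits into more than one weakly
   connected component and stays split for 50 consecutive snapshots (or to
   the end of a run that froze in a disconnected state: a stationary
   terminal state persists forever).  Subgroups are the weak components of
   the final graph.  Weak connectivity, not spatial clustering, is the
   criterion, because what disappears at fission is the information flow.
   A mid-run split that heals before the end is not fission.
2. **type 7** — the run reached stationarity in a *fully static*
   configuration: the final per-step displacement of every agent is below
   `stability_tol * d_e`.  This is rapid aggregation into a frozen
   cluster, typical of large `K` (especially `K = N-1`).  An early draft
   gated type 7 on stationarity arriving within `0.1*t_max`; measured
   settle times for near-complete topologies run to a third of `t_max`,
   so the static-displacement criterion replaced the time gate.
3. **type 8** — never stationary within `t_max` *and* the mean
   nearest-neighbour distance still drifts by more than `0.05*d_e` over
   the analysis window: motion that never organises.
4. **types 1-6** — from descending straightness cut points
   `S >= 0.9, 0.7, 0.45, 0.2, 0.05` for types 1-5; below that, helicity
   `>= 0.5` separates the purer torus (6) from its weaker counterpart (5).
   Only the *ordering* of S and H across types is pinned by the taxonomy,
   so all cut points live in `ClassifierConfig`, not in logic.

## Interaction network

Edges point from perceived neighbour to perceiver, so in-degree is `K` by
construction and out-degree measures influence.  Density is
`E/(N(N-1)) = K/(N-1)` identically.  Network entropy is the Shannon
entropy (nats) of the out-degree distribution — the in-degree distribution
is degenerate, so the out-degrees carry all the structure; this choice
reproduces the one pinned value (zero for the k-regular graph at
`K = N-1`).  Average geodesic distance is the mean directed shortest-path
length over reachable ordered pairs, with the reachable fraction reported
alongside (after fission, cross-subgroup distances are infinite and drop
out).  Clustering is the Watts–Strogatz local coefficient on the
undirected projection, since no directed variant is singled out by the
taxonomy.

## Scenario generators

All initial conditions are pure functions of a `ScenarioSpec` (seed
included), via `numpy.random.default_rng` (PCG64).

* `uniform_cloud` — uniform draws in a cube whose side is set from the
  Poisson nearest-neighbour law so the mean nearest-neighbour spacing hits
  the target (default 8.6, the saturation threshold) — the "loosely
  distributed" regime between `d_e` and `d_h` where attraction dominates
  the early dynamics.
* `isolated_individual` — an `N-1` cloud plus one agent at
  `isolation_offset` (default 20) from the cloud centroid, beyond the
  saturation threshold.
* `preformed_subgroups` — 2 or 3 pre-aggregated clouds (within-cloud
  spacing `d_e`) with centroids mutually `separation` apart (default 52,
  i.e. `10*d_e`), on a segment or equilateral triangle.

What the generators do *not* emulate: real groups have heterogeneous
perception, noise, and correlated (non-uniform) spatial structure.
Passing tests show the deterministic model's emergent phenomenology under
generic random initial conditions, not agreement with any empirical swarm.
Outcomes at small `K` are sensitive to the initial configuration: random
loose clouds readily fragment into several locally-formed clumps at
`K <= 4`, whereas more regular starting arrangements hold together longer.

## Experiment sizes

Sweep-style analyses (emergence thresholds, fission region, K/N
statistics) vote over a few seeded initial clouds per `(N, K)` cell:
10 seeds for the headline emergence scan at `N in {15, 16}`, 5 seeds per
cell for the fission sweep `N in {20..30} x K in {4..8}`, 3 seeds for the
across-N threshold scan at `N in {10, 15, 20, 25, 30, 40, 50}` (capped at
`K <= 8`), and 2 seeds per cell for the extended fission grid
`N in {35, 40, 45, 50} x K in {5, 8, 11, 14, 17, 20}`.  The K/N fission
statistics are computed over the union of the two fission grids rather
than the exhaustive `N <= 50` lattice.  Runs stop early at stationarity,
so a full sweep is dominated by the disordered and fission cells that use
all 20000 steps.  Per-cell seeds derive from
`SeedSequence((base_seed, N, K, replicate))`, so any cell can be
reproduced in isolation.

## Numerical choices and degenerate inputs

* Stationarity tolerance is absolute in units of `d_e` (`1e-6*d_e`);
  the two-body fixed-point check lands within `1e-4` of `d_e` because the
  contraction continues through the 50-step confirmation window.
* `K > N-1` is an error everywhere, never silently clamped.
* `K = 0` and `N = 1` are valid degenerate inputs: empty neighbour sets,
  zero force, immediate stationarity.
* Metrics requiring structure raise `UndefinedMetricError` below their
  minimum size (density/geodesic: N >= 2; clustering: N >= 3) instead of
  returning NaN.
* Graph snapshots for fission detection are taken every `store_stride`
  steps (default 10), so the 50-snapshot persistence window spans 500
  dynamics steps.

## Known limitations

* The taxonomy's 1-6 cut points are reporting conventions; different
  thresholds relabel borderline spiral runs without changing S or H.
* Fission is judged purely on graph connectivity.  Fragmentation into
  several small frozen clumps at very small `K` is therefore *also*
  fission by this definition, even though nothing ever "split" from an
  organised whole — at `K <= 2` the group often assembles directly into
  disconnected dimers and trimers.
* Helicity uses stored states (stride 10 by default); extremely fast
  rotation would alias, but the dynamics' per-step turning angles are far
  below that regime.
* No boundary conditions, noise, inertia or heterogeneity; the model is a
  minimal deterministic caricature designed to isolate what rank-based
  perception alone can produce.
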