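"""Order parameters, fission detection and the classification cascade.

These tests use constructed kinematic trajectories (positions prescribed
analytically, not simulated) so every expected value has a closed form.
"""

import numpy as np
import pytest

from toposwarm import (
    ClassifierConfig,
    ModelParams,
    SwarmState,
    build_graph,
    classify_motion,
    detect_fission,
    helicity,
    order_parameters,
    straightness,
)
from toposwarm.model_core import Trajectory


def kinematic_trajectory(frames, params, stationary_at=None):
    states = [SwarmState(f, step=t) for t, f in enumerate(frames)]
    return Trajectory(states, params, stationary_at=stationary_at)


def ring(n, radius=6.0, phase=0.0):
    ang = phase + 2 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])


def translating_frames(n_steps, n_agents=6, speed=0.5):
    base = ring(n_agents)
    v = np.array([1.0, 0.3, 0.1])
    v *= speed / np.linalg.norm(v)
    return [base + t * v for t in range(n_steps)]


def rotating_frames(n_steps, n_agents=6, omega=0.1):
    return [ring(n_agents, phase=omega * t) for t in range(n_steps)]


PARAMS6 = ModelParams(N=6, K=2)
FULL = (0, 40)


class TestStraightness:
    def test_straight_line_is_one(self):
        traj = kinematic_trajectory(translating_frames(40), PARAMS6)
        assert straightness(traj, FULL) == pytest.approx(1.0)

    def test_full_circle_is_zero(self):
        # one agent moving around a closed circle: zero net displacement
        p1 = ModelParams(N=1, K=0)
        ang = np.linspace(0, 2 * np.pi, 101)
        frames = [np.array([[np.cos(a), np.sin(a), 0.0]]) for a in ang]
        traj = kinematic_trajectory(frames, p1)
        assert straightness(traj, (0, 101)) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_chord_over_arc(self):
        p1 = ModelParams(N=1, K=0)
        ang = np.linspace(0, np.pi, 2001)
        frames = [np.array([[np.cos(a), np.sin(a), 0.0]]) for a in ang]
        traj = kinematic_trajectory(frames, p1)
        assert straightness(traj, (0, 2001)) == pytest.approx(2 / np.pi, abs=1e-5)

    def test_static_group_returns_zero(self):
        traj = kinematic_trajectory([ring(6)] * 40, PARAMS6)
        assert straightness(traj, FULL) == 0.0
        assert order_parameters(traj, FULL).stationary


class TestHelicity:
    def test_rigid_translation_is_zero(self):
        traj = kinematic_trajectory(translating_frames(40), PARAMS6)
        assert helicity(traj, FULL) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_is_one(self):
        # discrete displacements are chords: the exact value is cos(omega/2),
        # which tends to 1 as the per-step rotation angle shrinks
        traj = kinematic_trajectory(rotating_frames(40, omega=0.1), PARAMS6)
        assert helicity(traj, FULL) == pytest.approx(np.cos(0.05), abs=1e-9)
        fine = kinematic_trajectory(rotating_frames(400, omega=0.01), PARAMS6)
        assert helicity(fine, (0, 400)) == pytest.approx(1.0, abs=1e-4)

    def test_mixture_is_intermediate_and_monotone(self):
        # rotation plus translation: helicity strictly between 0 and 1,
        # decreasing as the translation weight grows
        vals = []
        for w in (0.0, 0.5, 1.0, 2.0, 4.0):
            frames = [
                ring(6, phase=0.1 * t) + w * t * np.array([0.6, 0, 0])
                for t in range(40)
            ]
            vals.append(helicity(kinematic_trajectory(frames, PARAMS6), FULL))
        assert vals[0] == pytest.approx(np.cos(0.05), abs=1e-9)  # pure rotation
        assert all(0.0 < v < 1.0 for v in vals[1:])
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_identical_displacements_give_zero(self, rng):
        # any shape translating rigidly has zero angular momentum
        base = rng.uniform(0, 10, (8, 3))
        frames = [base + t * np.array([0.2, -0.1, 0.4]) for t in range(30)]
        traj = kinematic_trajectory(frames, ModelParams(N=8, K=3))
        assert helicity(traj, (0, 30)) == pytest.approx(0.0, abs=1e-12)


class TestOrderParameterInvariance:
    @staticmethod
    def _mixture_frames(n_steps):
        # rotation plus drift: both order parameters strictly inside (0, 1)
        return [
            ring(6, phase=0.1 * t) + 0.3 * t * np.array([1.0, 0.2, 0.1])
            for t in range(n_steps)
        ]

    @pytest.mark.parametrize("builder", [translating_frames, _mixture_frames.__func__])
    def test_similarity_invariance(self, rng, builder):
        frames = builder(40)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-30, 30, 3)
        scale = 3.7
        moved = [scale * (f @ q.T) + shift for f in frames]
        a = kinematic_trajectory(frames, PARAMS6)
        b = kinematic_trajectory(moved, PARAMS6)
        assert straightness(a, FULL) == pytest.approx(straightness(b, FULL), abs=1e-9)
        assert helicity(a, FULL) == pytest.approx(helicity(b, FULL), abs=1e-9)


class TestDetectFission:
    def _graphs(self, frames, k):
        return [build_graph(SwarmState(f, step=t), k) for t, f in enumerate(frames)]

    def test_single_cluster_no_fission(self, rng):
        frames = [ring(8)] * 60
        step_, groups = detect_fission(self._graphs(frames, 3), window=50)
        assert step_ is None
        assert len(groups) == 1

    def test_two_separated_clusters(self, rng):
        # 12 + 11 agents, clusters 100*d_e apart, K=6: all six nearest
        # neighbours of every agent lie inside its own cluster
        a = rng.uniform(0, 15, (12, 3))
        b = rng.uniform(0, 15, (11, 3)) + np.array([520.0, 0, 0])
        frames = [np.vstack([a, b])] * 60
        step_, groups = detect_fission(self._graphs(frames, 6), window=50)
        assert step_ == 0
        assert sorted(map(len, groups)) == [11, 12]
        assert sorted(groups[0] + groups[1]) == list(range(23))

    def test_short_split_not_sustained(self, rng):
        a = rng.uniform(0, 15, (12, 3))
        b = rng.uniform(0, 15, (11, 3)) + np.array([520.0, 0, 0])
        split = np.vstack([a, b])
        merged = np.vstack([a, b - np.array([510.0, 0, 0])])
        frames = [split] * 10 + [merged] * 50
        step_, groups = detect_fission(self._graphs(frames, 6), window=50)
        assert step_ is None
        assert len(groups) == 1

    def test_stationary_terminal_split_counts(self, rng):
        # a frozen disconnected end state persists forever
        a = rng.uniform(0, 15, (12, 3))
        b = rng.uniform(0, 15, (11, 3)) + np.array([520.0, 0, 0])
        frames = [np.vstack([a, b])] * 5
        step_, groups = detect_fission(
            self._graphs(frames, 6), window=50, final_persists=True
        )
        assert step_ == 0
        assert len(groups) == 2


class TestClassificationCascade:
    def test_straight_translation_is_type_1(self):
        frames = translating_frames(80)
        traj = kinematic_trajectory(frames, PARAMS6)
        graphs = [build_graph(s, 2) for s in traj.states]
        report = classify_motion(traj, graphs, PARAMS6)
        assert report.motion_type == 1
        assert report.order.straightness > 0.99

    def test_pure_rotation_is_torus_type(self):
        frames = rotating_frames(80)
        traj = kinematic_trajectory(frames, PARAMS6)
        graphs = [build_graph(s, 2) for s in traj.states]
        report = classify_motion(traj, graphs, PARAMS6)
        assert report.motion_type in (5, 6)
        assert report.order.helicity > 0.9

    def test_static_stationary_run_is_type_7(self):
        frames = [ring(6)] * 80
        traj = kinematic_trajectory(frames, PARAMS6, stationary_at=0)
        graphs = [build_graph(s, 2) for s in traj.states]
        report = classify_motion(traj, graphs, PARAMS6)
        assert report.motion_type == 7

    def test_disorganised_run_is_type_8(self, rng):
        # never stationary and mean neighbour spacing keeps drifting
        frames = [rng.uniform(0, 30 + 5 * t, (6, 3)) for t in range(80)]
        traj = kinematic_trajectory(frames, PARAMS6, stationary_at=None)
        graphs = [build_graph(s, 2) for s in traj.states]
        report = classify_motion(traj, graphs, PARAMS6)
        assert report.motion_type in (8, "fission")

    def test_fission_preempts_other_types(self, rng):
        a = rng.uniform(0, 12, (6, 3))
        b = rng.uniform(0, 12, (6, 3)) + np.array([520.0, 0, 0])
        frames = [np.vstack([a, b]) + t * np.array([0.5, 0, 0]) for t in range(80)]
        p = ModelParams(N=12, K=3)
        traj = kinematic_trajectory(frames, p)
        graphs = [build_graph(s, 3) for s in traj.states]
        report = classify_motion(traj, graphs, p)
        assert report.motion_type == "fission"
        assert report.n_subgroups == 2
        assert report.fission_step == 0

    def test_thresholds_are_configuration(self):
        frames = translating_frames(80)
        traj = kinematic_trajectory(frames, PARAMS6)
        graphs = [build_graph(s, 2) for s in traj.states]
        # absurdly high first cut point pushes a straight line out of type 1
        cfg = ClassifierConfig(s_bounds=(1.1, 0.7, 0.45, 0.2, 0.05))
        report = classify_motion(traj, graphs, PARAMS6, cfg)
        assert report.motion_type == 2
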