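"""Replica-path construction, penalties, optimization and monitoring."""

import numpy as np
import pandas as pd
import pytest

from conftest import single_point_frame
from repath.geometry import Frame
from repath.path import (PathError, ReplicaPath, angle_penalty, energy_profile,
                         first_crossing, interpolate_endpoints, mean_rms,
                         monitor_distances, optimize_path, path_objective,
                         refine_endpoints, rms_spacing_penalty)
from repath.surfaces import PotentialSurface, harmonic


def frame(coords, weights=None):
    coords = np.asarray(coords, dtype=float)
    return Frame([f"p{i}" for i in range(len(coords))], coords, weights)


def chain_through(points_2d, **kw):
    kw.setdefault("fit", False)
    return ReplicaPath([single_point_frame(p) for p in points_2d], **kw)


class TestInterpolation:
    def test_midpoint_with_three_replicas(self):
        a = frame([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        b = frame([[2, 0, 0], [3, 0, 0], [2, 1, 0]])
        path = interpolate_endpoints(a, b, n_replicas=3)
        assert np.allclose(path.replicas[1].coords, (a.coords + b.coords) / 2)

    def test_sixteen_replicas_endpoints_exact(self):
        a = frame([[0, 0, 0], [1, 1, 1], [2, 0, 1]])
        b = frame([[5, 0, 0], [6, 1, 1], [7, 0, 1]])
        path = interpolate_endpoints(a, b, n_replicas=16)
        assert path.n_replicas == 16
        assert np.array_equal(path.replicas[0].coords, a.coords)
        assert np.array_equal(path.replicas[-1].coords, b.coords)

    def test_degenerate_endpoints_give_zero_segments(self):
        a = frame([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        path = interpolate_endpoints(a, a.copy(), n_replicas=5)
        assert np.allclose(path.segment_rms(), 0.0)

    def test_incompatible_frames_rejected(self):
        with pytest.raises(PathError, match="congruent"):
            interpolate_endpoints(frame([[0, 0, 0]]), frame([[0, 0, 0], [1, 0, 0]]))

    def test_default_parameters_are_protocol_values(self):
        a = frame([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        b = frame([[2, 0, 0], [3, 0, 0], [2, 1, 0]])
        path = interpolate_endpoints(a, b)
        assert (path.n_replicas, path.k_rms, path.k_angle, path.cosmax) == \
            (16, 2000.0, 100.0, 0.95)


class TestPenalties:
    def test_mean_rms_uniform_interpolation(self):
        path = chain_through([(0, 0), (1, 0), (2, 0), (3, 0)])
        seg = path.segment_rms()
        assert mean_rms(path) == pytest.approx(seg[0], rel=1e-12)
        assert np.allclose(seg, seg[0])

    def test_mean_rms_arithmetic_mean(self):
        path = chain_through([(0, 0), (1, 0), (3, 0)])  # segments 1 and 2
        assert mean_rms(path) == pytest.approx(1.5, rel=1e-12)

    def test_spacing_penalty_direct_evaluation(self):
        # segments {1, 2}: K · ((1−1.5)² + (2−1.5)²) = 2000 · 0.5 = 1000
        path = chain_through([(0, 0), (1, 0), (3, 0)], k_rms=2000.0)
        assert rms_spacing_penalty(path) == pytest.approx(1000.0, rel=1e-12)

    def test_spacing_penalty_zero_iff_uniform(self):
        assert rms_spacing_penalty(chain_through([(0, 0), (1, 0), (2, 0)])) == 0.0

    def test_spacing_penalty_linear_in_k(self):
        p1 = chain_through([(0, 0), (1, 0), (3, 0)], k_rms=2000.0)
        p2 = chain_through([(0, 0), (1, 0), (3, 0)], k_rms=4000.0)
        assert rms_spacing_penalty(p2) == pytest.approx(2 * rms_spacing_penalty(p1))

    def test_angle_penalty_zero_for_straight_path(self):
        assert angle_penalty(chain_through([(0, 0), (1, 0), (2, 0), (3, 0)])) == 0.0

    def test_angle_penalty_right_angle_kink(self):
        # cosθ = 0 at the kink: 100 · (0.95 − 0)² = 90.25
        path = chain_through([(0, 0), (1, 0), (1, 1)], k_angle=100.0, cosmax=0.95)
        assert angle_penalty(path) == pytest.approx(90.25, rel=1e-9)

    def test_angle_penalty_double_back(self):
        # cosθ = −1 when the path reverses: 100 · (1.95)² per vertex
        path = chain_through([(0, 0), (1, 0), (0, 0)], k_angle=100.0)
        assert angle_penalty(path) == pytest.approx(100 * 1.95**2, rel=1e-9)

    def test_zero_length_segment_rejected(self):
        path = chain_through([(0, 0), (0, 0), (1, 0)])
        with pytest.raises(PathError, match="zero-length segment"):
            angle_penalty(path)

    def test_rigid_motion_invariance_with_fit(self, rng):
        """One common rigid motion applied to every replica leaves both
        penalties unchanged when best-fit RMS distances are used."""
        frames = [frame(rng.normal(size=(5, 3))) for _ in range(6)]
        path = ReplicaPath(frames, fit=True)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(size=3)
        moved = ReplicaPath([f.with_coords(f.coords @ q.T + shift) for f in frames],
                            fit=True)
        assert rms_spacing_penalty(moved) == pytest.approx(
            rms_spacing_penalty(path), abs=1e-9)
        assert angle_penalty(moved) == pytest.approx(angle_penalty(path), abs=1e-9)

    def test_penalties_zero_on_uniform_straight_line(self):
        a = frame([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        b = frame([[4, 0, 0], [5, 0, 0], [4, 1, 0]])
        path = interpolate_endpoints(a, b, n_replicas=8, fit=False)
        assert rms_spacing_penalty(path) == pytest.approx(0.0, abs=1e-18)
        assert angle_penalty(path) == pytest.approx(0.0, abs=1e-18)


class TestObjective:
    def test_same_minimum_everywhere(self, mb_surface, mb_points):
        m = mb_points["minima"][0]
        path = chain_through([m["x"]] * 4)  # fully degenerate chain
        total, parts = path_objective(path, mb_surface)
        assert total == pytest.approx(4 * m["energy"], abs=1e-9)
        assert parts["rms_penalty"] == 0.0
        assert parts["angle_penalty"] == 0.0

    def test_penalties_off(self, mb_surface, rng):
        pts = rng.uniform(-1, 1, size=(5, 2))
        path = chain_through(pts, k_rms=0.0, k_angle=0.0)
        total, parts = path_objective(path, mb_surface)
        assert total == pytest.approx(parts["sum_replica_energy"], rel=1e-12)

    def test_parts_sum_to_total(self, mb_surface, rng):
        pts = rng.uniform(-1, 1, size=(7, 2))
        path = chain_through(pts)
        total, parts = path_objective(path, mb_surface)
        assert total == pytest.approx(sum(parts.values()), rel=1e-12)
        assert parts["rms_penalty"] == pytest.approx(rms_spacing_penalty(path), rel=1e-12)
        assert parts["angle_penalty"] == pytest.approx(angle_penalty(path), rel=1e-12)


def quadratic_valley():
    """Gentle 2D valley E = 0.05·x² + 2·y²: minimum line search scale where
    the spacing penalty dominates the energy term."""
    def energy(p):
        x, y = p
        return float(0.05 * x * x + 2.0 * y * y)

    def gradient(p):
        x, y = p
        return np.array([0.1 * x, 4.0 * y])

    return PotentialSurface("valley", 2, energy, gradient)


class TestOptimizePath:
    def test_straight_optimal_line_is_fixed_point(self):
        surf = quadratic_valley()
        path = interpolate_endpoints(single_point_frame((-1, 0)),
                                     single_point_frame((1, 0)),
                                     n_replicas=8, fit=False)
        opt, rep = optimize_path(path, surf, max_steps=2000)
        for before, after in zip(path.replicas, opt.replicas):
            assert np.allclose(before.coords, after.coords, atol=1e-4)

    def test_endpoints_bitwise_frozen(self, mb_optimized):
        init, opt = mb_optimized["initial"], mb_optimized["optimized"]
        assert np.array_equal(init.replicas[0].coords, opt.replicas[0].coords)
        assert np.array_equal(init.replicas[-1].coords, opt.replicas[-1].coords)

    def test_mb_barrier_against_grid_oracle(self, mb_optimized):
        saddle = mb_optimized["saddle"]
        refined = mb_optimized["refined"]
        prof = energy_profile(refined, __import__("repath.surfaces",
                                                  fromlist=["muller_brown"]).muller_brown())
        ts = refined.replicas[prof.ts_index].coords[0, :2]
        assert abs(prof.per_replica_energy.max() - saddle["energy"]) < 0.5
        assert np.linalg.norm(ts - saddle["x"]) < 0.1

    def test_objective_monotone_nonincreasing(self, mb_optimized):
        hist = np.array(mb_optimized["report"].objective_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_convergence_rule_patience(self, mb_optimized):
        """Converged only after 30 consecutive steps under both thresholds."""
        rep = mb_optimized["report"]
        assert rep.converged
        assert len(rep.objective_history) == rep.steps_taken
        assert len(rep.rms_gradient_history) == rep.steps_taken
        g = np.array(rep.rms_gradient_history[-30:])
        de = np.abs(np.diff(rep.objective_history[-31:]))
        assert np.all(g < 0.01)
        assert np.all(de < 1.0)

    def test_termination_at_max_steps(self, mb_surface, mb_points):
        m0, m1 = mb_points["minima"][2], mb_points["minima"][1]
        path = interpolate_endpoints(single_point_frame(m0["x"]),
                                     single_point_frame(m1["x"]),
                                     n_replicas=16, fit=False)
        opt, rep = optimize_path(path, mb_surface, max_steps=20)
        assert not rep.converged
        assert rep.steps_taken == 20
        assert "max_steps" in rep.convergence_reason

    def test_determinism(self, mb_surface, mb_points):
        m0, m1 = mb_points["minima"][2], mb_points["minima"][1]

        def run():
            path = interpolate_endpoints(single_point_frame(m0["x"]),
                                         single_point_frame(m1["x"]),
                                         n_replicas=8, fit=False)
            return optimize_path(path, mb_surface, max_steps=200)

        (p1, r1), (p2, r2) = run(), run()
        assert r1.objective_history == r2.objective_history
        assert r1.rms_gradient_history == r2.rms_gradient_history
        for a, b in zip(p1.replicas, p2.replicas):
            assert np.array_equal(a.coords, b.coords)

    def test_regular_spacing_where_penalty_dominates(self):
        surf = quadratic_valley()
        path = interpolate_endpoints(single_point_frame((-2, 0.3)),
                                     single_point_frame((2, -0.1)),
                                     n_replicas=10, fit=False)
        opt, rep = optimize_path(path, surf, max_steps=5000)
        assert rep.converged
        seg = opt.segment_rms()
        assert seg.std() / seg.mean() < 0.05


class TestRefinement:
    def test_window_spanning_whole_path_is_noop_refinement(self, mb_surface,
                                                           mb_optimized):
        opt = mb_optimized["optimized"]
        prof = energy_profile(opt, mb_surface)
        big = max(prof.ts_index, opt.n_replicas - 1 - prof.ts_index)
        refined = refine_endpoints(opt, mb_surface, window=big)
        lo = max(prof.ts_index - big, 0)
        hi = min(prof.ts_index + big, opt.n_replicas - 1)
        assert np.array_equal(refined.replicas[0].coords, opt.replicas[lo].coords)
        assert np.array_equal(refined.replicas[-1].coords, opt.replicas[hi].coords)

    def test_refinement_strictly_reduces_barrier_error(self, mb_surface,
                                                       mb_optimized):
        saddle = mb_optimized["saddle"]
        e1 = energy_profile(mb_optimized["optimized"], mb_surface).per_replica_energy.max()
        e2 = energy_profile(mb_optimized["refined"], mb_surface).per_replica_energy.max()
        assert abs(e2 - saddle["energy"]) < abs(e1 - saddle["energy"])

    def test_window_one_brackets_barrier(self, mb_surface, mb_optimized):
        opt = mb_optimized["optimized"]
        prof = energy_profile(opt, mb_surface)
        refined = refine_endpoints(opt, mb_surface, window=1)
        assert refined.n_replicas == 16
        assert np.array_equal(refined.replicas[0].coords,
                              opt.replicas[prof.ts_index - 1].coords)
        assert np.array_equal(refined.replicas[-1].coords,
                              opt.replicas[prof.ts_index + 1].coords)

    def test_ts_at_endpoint_refused(self, mb_surface):
        # monotone chain: the argmax energy sits on an endpoint
        path = chain_through([(-0.55, 1.44), (-0.6, 1.2), (-0.7, 0.9)])
        with pytest.raises(PathError, match="endpoint"):
            refine_endpoints(path, mb_surface)


class TestProfileAndMonitor:
    def test_flat_path_zero_activation(self, mb_surface, mb_points):
        m = mb_points["minima"][0]
        path = chain_through([m["x"], m["x"], m["x"]])
        prof = energy_profile(path, mb_surface)
        assert prof.activation_energy == 0.0
        assert prof.ts_index == 0  # tie broken to lowest index

    def test_monotone_profile_ts_at_end(self, mb_surface):
        path = chain_through([(0.62, 0.03), (0.5, 0.1), (0.35, 0.2)])
        prof = energy_profile(path, mb_surface)
        assert prof.ts_index == 2

    def test_monitor_coincident_pair_zero(self):
        f = frame([[0, 0, 0], [0, 0, 0], [1, 1, 1]])
        path = ReplicaPath([f.copy(), f.copy(), f.copy()], fit=False)
        table = monitor_distances(path, {"D": ("p0", "p1")})
        assert (table["D"] == 0.0).all()

    def test_monitor_linear_interpolation_monotone(self):
        a = frame([[0, 0, 0], [1, 0, 0], [5, 5, 5]])
        b = frame([[0, 0, 0], [3, 0, 0], [5, 5, 5]])
        path = interpolate_endpoints(a, b, n_replicas=5, fit=False)
        table = monitor_distances(path, {"R": ("p0", "p1")})
        assert table["R"].iloc[0] == pytest.approx(1.0)
        assert table["R"].iloc[-1] == pytest.approx(3.0)
        assert (table["R"].diff().dropna() > 0).all()

    def test_monitor_unknown_label_rejected(self):
        f = frame([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        path = ReplicaPath([f.copy(), f.copy(), f.copy()], fit=False)
        with pytest.raises(Exception, match="nope"):
            monitor_distances(path, {"R": ("p0", "nope")})

    def test_first_crossing(self):
        table = pd.DataFrame({"replica": [1, 2, 3, 4], "R": [1.0, 1.8, 2.4, 3.0]})
        assert first_crossing(table, "R", 2.0, above=True) == 3
        assert first_crossing(table, "R", 1.5, above=False) == 1
        assert first_crossing(table, "R", 9.0, above=True) is None
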