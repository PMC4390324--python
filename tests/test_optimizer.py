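"""Objective/constraint evaluation, SA + Hooke-Jeeves search and selection."""

import math
from dataclasses import dataclass, field

import numpy as np
import pytest

import tendonfit as tf
from tendonfit.data import (
    SyntheticSpec,
    generate_synthetic_targets,
    make_problem,
    muscle_path_from_table,
    pair_vector,
)
from tendonfit.optimizer import (
    Candidate,
    HJSettings,
    SASchedule,
    hooke_jeeves,
    make_start_points,
    multi_start_fit,
    path_curvature_radius,
    radius_of_curvature,
    select_candidate,
    simulated_annealing,
)

FAST_SA = SASchedule(max_temps=8, cycles=8, step_adjusts=3)


@dataclass
class SurrogateProblem:
    """Analytic stand-in exposing the interface the searchers rely on."""

    cost_fn: callable
    lb: np.ndarray
    ub: np.ndarray
    seed: int = 0
    sa: SASchedule = field(default_factory=lambda: FAST_SA)
    hj: HJSettings = field(default_factory=HJSettings)
    x0_list: tuple = ()
    measured_x: np.ndarray | None = None

    def clip(self, x):
        return np.clip(x, self.lb, self.ub)

    def penalized(self, x):
        f = float(self.cost_fn(np.asarray(x, dtype=float)))
        return f, f, 0.0

    def candidate(self, x, n_evals=0):
        f = float(self.cost_fn(np.asarray(x, dtype=float)))
        return Candidate(np.asarray(x, dtype=float).copy(), f, 0.0, float("nan"),
                         float("inf"), True, n_evals)


def quadratic_bowl(x_star):
    return lambda x: float(np.sum((x - x_star) ** 2))


@pytest.fixture(scope="module")
def fds_problem():
    """Index FDS at MCP with targets generated from the packaged attachments."""
    fixtures = tf.load_fixtures()
    chain = tf.build_finger_chain(finger=2)
    path = muscle_path_from_table(fixtures.attachments, 2, "FDS", "optimized")
    truth = pair_vector(path, "MCP")
    targets = generate_synthetic_targets(SyntheticSpec(path, 0.0, 100, 0), chain)
    targets = [t for t in targets if t.joint == "MCP"]
    problem = make_problem(chain, path, "MCP", targets, seed=11,
                           n_starts=6, sa=FAST_SA)
    return problem, truth


class TestObjective:
    def test_truth_attains_zero(self, fds_problem):
        problem, truth = fds_problem
        assert tf.objective_f(truth, problem) == pytest.approx(0.0, abs=1e-12)
        assert problem.penalized(truth)[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_offset_rms(self, fds_problem):
        """Shifting the target curve by delta shifts the RMS objective to delta."""
        problem, truth = fds_problem
        delta = 1.75
        shifted = [
            tf.MomentArmCurve(t.joint, t.dof, t.angles, t.values + delta, t.source)
            if t.dof == "flexion" else t
            for t in problem.targets
        ]
        p2 = make_problem(problem.chain, problem.path_template, "MCP", shifted, seed=11)
        assert tf.objective_f(truth, p2) == pytest.approx(delta, abs=1e-9)

    def test_matches_brute_force_recomputation(self, fds_problem, rng):
        """The vectorized objective equals a loop over the generic
        partial-velocity moment arm at every grid posture."""
        problem, truth = fds_problem
        flex_target = next(t for t in problem.targets if t.dof == "flexion")
        for _ in range(5):
            x = rng.uniform(problem.lb, problem.ub)
            path = problem.path_template.with_pair("MCP", x[:3], x[3:])
            _, postures = tf.posture_grid(problem.chain, "MCP", "flexion", problem.m)
            model = np.array([
                tf.moment_arm(problem.chain, q, path, "MCP", "flexion",
                              wraps=problem.wraps)
                for q in postures
            ])
            brute = math.sqrt(float(np.mean((flex_target.values - model) ** 2)))
            assert tf.objective_f(x, problem) == pytest.approx(brute, abs=1e-9)

    def test_grid_mismatch_rejected(self, fds_problem):
        problem, _ = fds_problem
        bad = tf.MomentArmCurve("MCP", "flexion", np.linspace(0, 90, 50), np.ones(50))
        with pytest.raises(ValueError, match="grid size"):
            make_problem(problem.chain, problem.path_template, "MCP", [bad], m=100)


class TestConstraint:
    def _offset_problem(self, chain, fixtures, muscle, offset):
        path = muscle_path_from_table(fixtures.attachments, 2, muscle, "optimized")
        truth = pair_vector(path, "MCP")
        targets = [t for t in generate_synthetic_targets(
            SyntheticSpec(path, 0.0, 100, 0), chain) if t.joint == "MCP"]
        targets = [
            tf.MomentArmCurve(t.joint, t.dof, t.angles, t.values + offset, t.source)
            if t.dof == "abduction" else t
            for t in targets
        ]
        problem = make_problem(chain, path, "MCP", targets, seed=0)
        return problem, np.clip(truth, problem.lb, problem.ub)

    def test_matched_abduction_attains_zero(self, index_chain, fixtures):
        problem, truth = self._offset_problem(index_chain, fixtures, "FDS", 0.0)
        assert tf.constraint_g(truth, problem) == pytest.approx(0.0, abs=1e-9)
        assert problem.candidate(truth).feasible

    def test_offset_3mm_infeasible_at_extrinsic_epsilon(self, index_chain, fixtures):
        problem, truth = self._offset_problem(index_chain, fixtures, "FDS", 3.0)
        assert problem.epsilon == 2.5  # FDS is extrinsic
        assert tf.constraint_g(truth, problem) == pytest.approx(3.0, abs=1e-9)
        assert not problem.candidate(truth).feasible

    def test_offset_1p6mm_feasible_at_intrinsic_epsilon(self, index_chain, fixtures):
        problem, truth = self._offset_problem(index_chain, fixtures, "LU", 1.6)
        assert problem.epsilon == 1.7  # LU is intrinsic
        assert tf.constraint_g(truth, problem) == pytest.approx(1.6, abs=1e-9)
        assert problem.candidate(truth).feasible

    def test_experimental_style_curve_reduces_to_mean_level(self, index_chain, fixtures):
        """An ab/adduction target tabulated over the ab/adduction range is
        held to its mean level during the flexion sweep."""
        path = muscle_path_from_table(fixtures.attachments, 2, "FDS", "optimized")
        targets = [t for t in generate_synthetic_targets(
            SyntheticSpec(path, 0.0, 100, 0), index_chain)
            if t.joint == "MCP" and t.dof == "flexion"]
        level = 2.2
        targets.append(tf.MomentArmCurve("MCP", "abduction", np.linspace(0, 30, 50),
                                         np.full(50, level)))
        problem = make_problem(index_chain, path, "MCP", targets, seed=0)
        x = np.clip(pair_vector(path, "MCP"), problem.lb, problem.ub)
        model = problem._model.abduction_values(x)
        expected = math.sqrt(float(np.mean((level - model) ** 2)))
        assert tf.constraint_g(x, problem) == pytest.approx(expected, abs=1e-12)

    def test_vacuous_at_revolute_joints(self, index_chain, fixtures):
        path = muscle_path_from_table(fixtures.attachments, 2, "FDP", "optimized")
        targets = [t for t in generate_synthetic_targets(
            SyntheticSpec(path, 0.0, 100, 0), index_chain) if t.joint == "DIP"]
        problem = make_problem(index_chain, path, "DIP", targets, seed=0)
        assert tf.constraint_g(pair_vector(path, "DIP"), problem) == 0.0


class TestSimulatedAnnealing:
    def test_finds_quadratic_minimum(self):
        x_star = np.array([1.0, -2.0, 0.5, 3.0, -1.5, 2.0])
        prob = SurrogateProblem(quadratic_bowl(x_star),
                                lb=np.full(6, -5.0), ub=np.full(6, 5.0), seed=3)
        cand = simulated_annealing(prob, np.zeros(6), seed=3)
        refined = hooke_jeeves(prob, cand.x)
        assert np.all(np.abs(refined.x - x_star) < 0.01)

    def test_same_seed_identical_trajectory(self, fds_problem):
        problem, truth = fds_problem
        x0 = problem.x0_list[3]
        a = simulated_annealing(problem, x0, seed=42)
        b = simulated_annealing(problem, x0, seed=42)
        assert np.array_equal(a.x, b.x) and a.f_value == b.f_value

    def test_iterates_respect_bounds(self):
        seen = []

        def spy(x):
            seen.append(x.copy())
            return float(np.sum(x**2))

        prob = SurrogateProblem(spy, lb=np.full(6, -1.0), ub=np.full(6, 2.0), seed=1)
        simulated_annealing(prob, np.full(6, 1.9), seed=1)
        arr = np.array(seen)
        assert np.all(arr >= -1.0 - 1e-12) and np.all(arr <= 2.0 + 1e-12)

    def test_recovers_known_attachments_without_noise(self, fds_problem):
        problem, truth = fds_problem
        cand = simulated_annealing(problem, problem.x0_list[2], seed=5)
        refined = hooke_jeeves(problem, cand.x)
        assert refined.f_value < 0.1


class TestHookeJeeves:
    def test_quadratic_bowl_to_final_step(self):
        x_star = np.array([0.3, -0.7, 1.1, -2.2, 0.0, 0.9])
        prob = SurrogateProblem(quadratic_bowl(x_star),
                                lb=np.full(6, -5.0), ub=np.full(6, 5.0))
        cand = hooke_jeeves(prob, np.zeros(6))
        assert np.all(np.abs(cand.x - x_star) <= 2e-3)

    def test_start_at_optimum_returns_start(self):
        x_star = np.full(6, 0.5)
        prob = SurrogateProblem(quadratic_bowl(x_star),
                                lb=np.full(6, -5.0), ub=np.full(6, 5.0))
        cand = hooke_jeeves(prob, x_star)
        np.testing.assert_array_equal(cand.x, x_star)
        assert cand.f_value == 0.0

    def test_refines_sa_output(self, rng):
        """Pattern search never degrades the annealing result."""
        for k in range(20):
            x_star = rng.uniform(-3, 3, 6)
            prob = SurrogateProblem(quadratic_bowl(x_star),
                                    lb=np.full(6, -5.0), ub=np.full(6, 5.0), seed=k)
            sa = simulated_annealing(prob, rng.uniform(-5, 5, 6), seed=k)
            hj = hooke_jeeves(prob, sa.x)
            assert hj.f_value <= sa.f_value + 1e-15


class TestMultiStart:
    def test_convex_surrogate_all_starts_agree(self, rng):
        x_star = np.array([0.5, 1.0, -1.0, 0.0, 2.0, -2.0])
        starts = tuple(rng.uniform(-5, 5, 6) for _ in range(6))
        prob = SurrogateProblem(quadratic_bowl(x_star), lb=np.full(6, -5.0),
                                ub=np.full(6, 5.0), seed=9, x0_list=starts)
        cands = multi_start_fit(prob)
        for c in cands:
            assert np.all(np.abs(c.x - x_star) < 0.01)

    def test_seeded_run_repeats_identically(self, fds_problem):
        problem, _ = fds_problem
        a = multi_start_fit(problem)
        b = multi_start_fit(problem)
        assert len(a) == len(b) == 6
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.x, cb.x)
            assert ca.f_value == cb.f_value and ca.feasible == cb.feasible

    def test_two_basin_problem_recovers_both_minima(self):
        m1, m2 = np.full(6, -2.0), np.full(6, 2.0)

        def two_basins(x):
            return min(float(np.sum((x - m1) ** 2)), float(np.sum((x - m2) ** 2)))

        starts = tuple(np.full(6, v) for v in (-4.0, -1.0, 1.0, 4.0, -3.0, 3.0))
        prob = SurrogateProblem(two_basins, lb=np.full(6, -5.0), ub=np.full(6, 5.0),
                                seed=2, x0_list=starts)
        ends = {tuple(np.round(c.x)) for c in multi_start_fit(prob)}
        assert len(ends) >= 2

    def test_start_points_measured_first_then_fill(self):
        lb, ub = np.full(6, -1.0), np.full(6, 1.0)
        measured = np.zeros(6)
        starts = make_start_points((lb, ub), measured, 26, seed=4)
        assert len(starts) == 26
        np.testing.assert_array_equal(starts[0], measured)
        assert all(np.all((s >= lb) & (s <= ub)) for s in starts)


class TestCurvature:
    def test_unit_circle_points(self, rng):
        th = rng.uniform(0, 2 * np.pi, 3)
        pts = [np.array([np.cos(t), np.sin(t), 0.0]) for t in th]
        if min(np.linalg.norm(pts[i] - pts[j]) for i in range(3) for j in range(i)) > 1e-3:
            assert radius_of_curvature(*pts) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_is_infinite(self):
        assert radius_of_curvature([0, 0, 0], [1, 1, 1], [2, 2, 2]) == float("inf")

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            radius_of_curvature([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_matches_circumcentre_construction(self, rng):
        """Independent oracle: solve for the circumcentre from the two
        perpendicular-bisector equations, then take the distance."""
        for _ in range(25):
            p1, p2, p3 = rng.uniform(-10, 10, (3, 3))
            n1, n2 = p2 - p1, p3 - p1
            a = np.array([n1, n2, np.cross(n1, n2)])
            if abs(np.linalg.det(a)) < 1e-6:
                continue
            b = np.array([n1 @ (p1 + p2) / 2, n2 @ (p1 + p3) / 2, np.cross(n1, n2) @ p1])
            centre = np.linalg.solve(a, b)
            assert radius_of_curvature(p1, p2, p3) == pytest.approx(
                float(np.linalg.norm(centre - p1)), rel=1e-6)

    def test_multi_pair_path_curvature_finite(self, index_chain, fixtures):
        path = muscle_path_from_table(fixtures.attachments, 2, "FDP", "optimized")
        r = path_curvature_radius(index_chain, path)
        assert 0 < r < float("inf")


class TestSelection:
    def _cand(self, x, f, delta, curv, feasible=True):
        return Candidate(np.asarray(x, float), f, 0.0, delta, curv, feasible)

    def test_smoothest_within_threshold_wins(self):
        # index threshold = 0.28 * 25.10 = 7.03 mm: both are inside, so the
        # larger curvature radius wins regardless of distance
        a = self._cand(np.zeros(6), 0.5, 5.0, 40.0)
        b = self._cand(np.ones(6), 0.4, 6.0, 90.0)
        chosen = select_candidate([a, b], middle_phalanx_length=25.10)
        assert chosen is b

    def test_none_within_threshold_takes_nearest(self):
        a = self._cand(np.zeros(6), 0.1, 9.0, 500.0)
        b = self._cand(np.ones(6), 0.9, 8.0, 1.0)
        assert select_candidate([a, b], middle_phalanx_length=25.10) is b

    def test_single_candidate(self):
        a = self._cand(np.zeros(6), 1.0, 2.0, 3.0)
        assert select_candidate([a], middle_phalanx_length=25.10) is a

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_candidate([], middle_phalanx_length=25.10)

    def test_matches_brute_force_rule(self, rng):
        """Exhaustive re-application of the selection rule on random sets."""
        thr = 0.28 * 25.10
        for _ in range(100):
            n = int(rng.integers(1, 8))
            cands = [
                self._cand(rng.uniform(-1, 1, 6), float(rng.uniform(0, 3)),
                           float(rng.uniform(0, 12)), float(rng.uniform(1, 200)),
                           bool(rng.random() < 0.8))
                for _ in range(n)
            ]
            chosen = select_candidate(cands, middle_phalanx_length=25.10)
            pool = [c for c in cands if c.feasible] or cands
            close = [c for c in pool if c.delta_r <= thr]
            if close:
                expect = max(close, key=lambda c: (c.curvature_radius, -c.f_value))
            else:
                expect = min(pool, key=lambda c: (c.delta_r, c.f_value))
            assert chosen is expect

    def test_infeasible_preferred_only_as_fallback(self):
        feas = self._cand(np.zeros(6), 2.0, 6.0, 5.0, feasible=True)
        infeas = self._cand(np.ones(6), 0.1, 1.0, 500.0, feasible=False)
        assert select_candidate([feas, infeas], middle_phalanx_length=25.10) is feas
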