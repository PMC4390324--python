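"""Attachment-placement optimization.

One attachment pair (proximal + distal point, x in R^6) is freed and moved
so that the model moment arms at the joint it straddles match target
moment-arm curves.  The fit minimizes

    f(x) = sum over target curves of sqrt( sum_i [r(q_i) - r_hat(q_i, x)]^2 / m )

subject to box bounds lb <= x <= ub (the skin-surface box around each bone)
and, at the MCP joint, an inequality constraint g(x) <= eps on the RMS
deviation of the ab/adduction moment arm over the flexion sweep, with eps
the measurement standard deviation (2.5 mm extrinsic, 1.7 mm intrinsic
muscles).  The constraint is handled by an exterior quadratic penalty
(1e4 * max(0, g - eps)^2) during the search plus a hard feasibility flag on
the returned candidates.

The search is multi-start: Corana-style adaptive Simulated Annealing from
each of 26 starting points (the measured pair plus seeded uniform samples
within the bounds), each refined by Hooke-Jeeves pattern search.  Among
candidates whose distance to the measured pair is within 28% of the
middle-phalanx length, the smoothest tendon path (largest radius of
curvature over successive attachments) is selected; otherwise the candidate
nearest the measured pair wins, with ties broken by objective value.

Vector layout: x = (proximal xyz, distal xyz), mm, in the frames of the
segments the pair rides on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinematics import FingerChain, Posture, ZERO_POSTURE
from .musclepath import (
    MomentArmCurve,
    MusclePath,
    WrapCylinder,
    default_wrap_set,
    epsilon_for,
    resolve_path,
)

__all__ = [
    "PairGridModel",
    "OptProblem",
    "Candidate",
    "SASchedule",
    "HJSettings",
    "objective_f",
    "constraint_g",
    "penalized",
    "simulated_annealing",
    "hooke_jeeves",
    "multi_start_fit",
    "make_start_points",
    "radius_of_curvature",
    "path_curvature_radius",
    "select_candidate",
    "PENALTY_WEIGHT",
]

PENALTY_WEIGHT = 1e4
TWO_PI = 2.0 * math.pi


class PairGridModel:
    """Vectorized moment arms of a single attachment pair over an angle grid.

    Produces exactly the same numbers as :func:`tendonfit.musclepath.moment_arm`
    (partial-velocity method) for a two-point pair straddling ``joint``:
    flexion moment arms include the joint's wrap cylinder; ab/adduction
    moment arms use the straight chord (no ab/adduction wrap geometry).
    """

    def __init__(
        self,
        chain: FingerChain,
        joint: str,
        wrap: WrapCylinder | None = None,
        m: int = 100,
    ):
        self.chain = chain
        self.joint = joint
        self.wrap = wrap
        ji = chain.joint_index(joint)
        self.offset = chain.joint_offset(ji)
        spec = chain.joint(joint)
        lo, hi = spec.dof("flexion").rom_deg
        self.flex_deg = np.linspace(lo, hi, m)
        th = np.radians(self.flex_deg)
        self._cos, self._sin = np.cos(th), np.sin(th)
        self.has_abduction = "abduction" in spec.dof_names
        self.m = m

    def _geometry(self, x: np.ndarray):
        px, py, pz = x[0], x[1] + self.offset, x[2]  # proximal, rel joint centre
        dx, dy, dz = x[3], x[4], x[5]  # distal, child frame = rel centre
        d_y = dy * self._cos - dz * self._sin
        d_z = dy * self._sin + dz * self._cos
        return px, py, pz, dx, d_y, d_z

    def flexion_values(self, x: np.ndarray) -> np.ndarray:
        px, py, pz, dx, d_y, d_z = self._geometry(x)
        ex, ey, ez = dx - px, d_y - py, d_z - pz
        norm = np.maximum(np.sqrt(ex * ex + ey * ey + ez * ez), 1e-12)
        ma = (ey * d_z - ez * d_y) / norm  # -u . (x_hat x D)
        if self.wrap is None:
            return ma
        r = self.wrap.radius
        dp = math.hypot(py, pz)
        dd = math.hypot(x[4], x[5])
        if dp <= r or dd <= r:
            return ma
        cross = py * d_z - pz * d_y
        elen = np.sqrt(ey * ey + ez * ez)
        with np.errstate(invalid="ignore", divide="ignore"):
            line_dist = np.abs(cross) / elen
            t_foot = -(py * ey + pz * ez) / (elen * elen)
        th_p = math.atan2(pz, py)
        th_d = np.arctan2(d_z, d_y)
        delta_ccw = np.mod(th_d - th_p, TWO_PI)
        side_angle = -0.5 * math.pi if self.wrap.side == "palmar" else 0.5 * math.pi
        passes = np.mod(side_angle - th_p, TWO_PI) <= delta_ccw
        delta = np.where(passes, delta_ccw, delta_ccw - TWO_PI)
        beta_p = math.acos(r / dp)
        beta_d = math.acos(r / dd)
        sweep = np.abs(delta) - beta_p - beta_d
        engaged = (line_dist < r) & (t_foot > 0.0) & (t_foot < 1.0) & (sweep > 0.0)
        if not np.any(engaged):
            return ma
        t_p = math.sqrt(dp * dp - r * r)
        t_d = math.sqrt(dd * dd - r * r)
        lp = t_p + r * sweep + t_d
        h = dx - px
        sign = 1.0 if self.wrap.side == "palmar" else -1.0
        ma_wrap = sign * r * lp / np.sqrt(lp * lp + h * h)
        return np.where(engaged, ma_wrap, ma)

    def abduction_values(self, x: np.ndarray) -> np.ndarray:
        """Straight-chord ab/adduction moment arm over the flexion sweep."""
        if not self.has_abduction:
            return np.zeros(self.m)
        px, py, pz, dx, d_y, d_z = self._geometry(x)
        ex, ey, ez = dx - px, d_y - py, d_z - pz
        norm = np.maximum(np.sqrt(ex * ex + ey * ey + ez * ez), 1e-12)
        return (ex * d_y - ey * dx) / norm  # -u . (z_hat x D)


@dataclass(frozen=True)
class SASchedule:
    """Corana-style annealing schedule."""

    t0: float = 10.0
    cooling: float = 0.85
    cycles: int = 20  # moves per coordinate per step adjustment
    step_adjusts: int = 5  # step adjustments per temperature
    f_tol: float = 1e-4
    n_tol: int = 4  # consecutive temperatures within f_tol to stop
    max_temps: int = 40
    step0_frac: float = 0.25  # initial step as a fraction of the box width


@dataclass(frozen=True)
class HJSettings:
    step0: float = 1.0  # mm
    min_step: float = 1e-3  # mm
    max_evals: int = 20000


@dataclass
class OptProblem:
    """One free attachment pair fitted to target moment-arm curves."""

    chain: FingerChain
    path_template: MusclePath
    free_joint: str
    targets: tuple[MomentArmCurve, ...]  # flexion target(s); optional abduction target
    lb: np.ndarray
    ub: np.ndarray
    epsilon: float
    m: int = 100
    seed: int = 0
    measured_x: np.ndarray | None = None
    x0_list: tuple[np.ndarray, ...] = ()
    wraps: dict[str, WrapCylinder] | None = None
    sa: SASchedule = field(default_factory=SASchedule)
    hj: HJSettings = field(default_factory=HJSettings)

    _model: PairGridModel = field(init=False, repr=False)
    _flex_targets: list[np.ndarray] = field(init=False, repr=False)
    _abd_target: np.ndarray | None = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.lb.shape != (6,) or self.ub.shape != (6,):
            raise ValueError("bounds must be 6-vectors (proximal xyz, distal xyz)")
        if not np.all(self.lb < self.ub):
            raise ValueError("lb must be strictly below ub componentwise")
        if self.wraps is None:
            self.wraps = default_wrap_set(self.chain, self.path_template.muscle)
        wrap = self.wraps.get(self.free_joint)
        self._model = PairGridModel(self.chain, self.free_joint, wrap, self.m)
        self._flex_targets = []
        self._abd_target = None
        for t in self.targets:
            if t.dof == "flexion":
                if t.values.size != self.m:
                    raise ValueError(
                        f"target grid size {t.values.size} does not match m={self.m}"
                    )
                self._flex_targets.append(np.asarray(t.values, dtype=float))
            elif t.dof == "abduction":
                vals = np.asarray(t.values, dtype=float)
                angles = np.asarray(t.angles, dtype=float)
                if vals.size == self.m and np.allclose(angles, self._model.flex_deg):
                    # target indexed by the flexion sweep: compare pointwise
                    self._abd_target = vals
                else:
                    # experimental-style curve over the ab/adduction range:
                    # hold the model to its mean level during flexion
                    self._abd_target = np.full(self.m, float(vals.mean()))
            else:
                raise ValueError(f"unknown target dof {t.dof!r}")
        if not self._flex_targets:
            raise ValueError("at least one flexion target curve is required")
        if self.x0_list:
            self.x0_list = tuple(np.asarray(x, dtype=float) for x in self.x0_list)
            for x0 in self.x0_list:
                if not np.all((x0 >= self.lb) & (x0 <= self.ub)):
                    raise ValueError("start point outside bounds")

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def penalized(self, x: np.ndarray) -> tuple[float, float, float]:
        """(search cost, f, g) at x; the cost adds the constraint penalty."""
        return penalized(x, self)

    def candidate(self, x: np.ndarray, n_evals: int = 0) -> "Candidate":
        return _candidate(self, x, n_evals)


@dataclass(frozen=True)
class Candidate:
    x: np.ndarray
    f_value: float  # summed RMS objective, mm
    g_value: float  # ab/adduction RMS, mm
    delta_r: float  # worst point distance to the measured pair, mm (nan if unknown)
    curvature_radius: float  # mm, inf for straight/two-point paths
    feasible: bool
    n_evals: int = 0


def objective_f(x: np.ndarray, problem: OptProblem) -> float:
    """Summed RMS moment-arm error (mm) over the flexion target curves."""
    x = np.asarray(x, dtype=float)
    model = problem._model.flexion_values(x)
    return float(
        sum(math.sqrt(float(np.mean((t - model) ** 2))) for t in problem._flex_targets)
    )


def constraint_g(x: np.ndarray, problem: OptProblem) -> float:
    """RMS ab/adduction moment-arm deviation over the flexion sweep (mm).

    Vacuous (0) at joints without an ab/adduction DOF or without an
    ab/adduction target.
    """
    if problem._abd_target is None or not problem._model.has_abduction:
        return 0.0
    model = problem._model.abduction_values(np.asarray(x, dtype=float))
    return float(math.sqrt(float(np.mean((problem._abd_target - model) ** 2))))


def penalized(x: np.ndarray, problem: OptProblem) -> tuple[float, float, float]:
    f = objective_f(x, problem)
    g = constraint_g(x, problem)
    return f + PENALTY_WEIGHT * max(0.0, g - problem.epsilon) ** 2, f, g


def _candidate(problem: OptProblem, x: np.ndarray, n_evals: int) -> Candidate:
    _, f, g = penalized(x, problem)
    feasible = bool(
        np.all((x >= problem.lb - 1e-12) & (x <= problem.ub + 1e-12))
        and g <= problem.epsilon + 1e-12
    )
    if problem.measured_x is not None:
        mx = np.asarray(problem.measured_x, dtype=float)
        delta = max(
            float(np.linalg.norm(x[:3] - mx[:3])), float(np.linalg.norm(x[3:] - mx[3:]))
        )
    else:
        delta = float("nan")
    path = problem.path_template.with_pair(problem.free_joint, x[:3], x[3:])
    curv = path_curvature_radius(problem.chain, path)
    return Candidate(x.copy(), f, g, delta, curv, feasible, n_evals)


def simulated_annealing(
    problem: OptProblem, x0: np.ndarray, seed: int | None = None
) -> Candidate:
    """Adaptive simulated annealing with per-coordinate step control.

    All iterates are clipped to the bounds; the best point ever seen is
    returned, so the result never degrades the start.  The trajectory is a
    deterministic function of the seed.
    """
    s = problem.sa
    rng = np.random.default_rng(problem.seed if seed is None else seed)
    x = problem.clip(np.asarray(x0, dtype=float).copy())
    fx, _, _ = problem.penalized(x)
    best_x, best_f = x.copy(), fx
    width = problem.ub - problem.lb
    step = s.step0_frac * width
    temp = s.t0
    history: list[float] = []
    evals = 0
    for _ in range(s.max_temps):
        for _ in range(s.step_adjusts):
            accepted = np.zeros(6)
            for _ in range(s.cycles):
                for i in range(6):
                    xc = x.copy()
                    xc[i] += rng.uniform(-1.0, 1.0) * step[i]
                    xc = problem.clip(xc)
                    fc, _, _ = problem.penalized(xc)
                    evals += 1
                    if fc <= fx or rng.random() < math.exp(-(fc - fx) / temp):
                        x, fx = xc, fc
                        accepted[i] += 1
                        if fc < best_f:
                            best_x, best_f = xc.copy(), fc
            # Corana step adaptation toward ~50% acceptance per coordinate
            ratio = accepted / s.cycles
            grow = ratio > 0.6
            shrink = ratio < 0.4
            step = np.where(grow, step * (1.0 + 2.0 * (ratio - 0.6) / 0.4), step)
            step = np.where(shrink, step / (1.0 + 2.0 * (0.4 - ratio) / 0.4), step)
            step = np.minimum(step, width)
        history.append(fx)
        temp *= s.cooling
        x, fx = best_x.copy(), best_f  # re-anneal from the incumbent
        if len(history) > s.n_tol and all(
            abs(history[-1] - history[-1 - k]) < s.f_tol for k in range(1, s.n_tol + 1)
        ) and abs(history[-1] - best_f) < s.f_tol:
            break
    return problem.candidate(best_x, evals)


def hooke_jeeves(problem: OptProblem, x0: np.ndarray) -> Candidate:
    """Deterministic pattern search: exploratory + pattern moves, halving steps."""
    s = problem.hj

    def cost(x):
        return problem.penalized(x)[0]

    x = problem.clip(np.asarray(x0, dtype=float).copy())
    fx = cost(x)
    evals = 1
    step = s.step0

    def explore(base: np.ndarray, f_base: float):
        nonlocal evals
        x_new, f_new = base.copy(), f_base
        for i in range(6):
            for delta in (step, -step):
                trial = x_new.copy()
                trial[i] = min(max(trial[i] + delta, problem.lb[i]), problem.ub[i])
                if trial[i] == x_new[i]:
                    continue
                f_trial = cost(trial)
                evals += 1
                if f_trial < f_new:
                    x_new, f_new = trial, f_trial
                    break
        return x_new, f_new

    while step >= s.min_step and evals < s.max_evals:
        f_before = fx
        x_e, f_e = explore(x, fx)
        if f_e < fx:
            # pattern move along the successful direction, then re-explore
            pattern_iters = 0
            while evals < s.max_evals and pattern_iters < 100:
                pattern_iters += 1
                x_p = problem.clip(x_e + (x_e - x))
                x, fx = x_e, f_e
                x_e, f_e = explore(x_p, cost(x_p))
                evals += 1
                if f_e >= fx:
                    break
            if f_e < fx:
                x, fx = x_e, f_e
            # negligible gain at this step size: zig-zag stagnation, shrink
            if f_before - fx < 1e-10 * (1.0 + abs(f_before)):
                step *= 0.5
        else:
            step *= 0.5
    return problem.candidate(x, evals)


def make_start_points(
    problem_bounds: tuple[np.ndarray, np.ndarray],
    measured_x: np.ndarray | None,
    n: int = 26,
    seed: int = 0,
    extra: Sequence[np.ndarray] = (),
) -> list[np.ndarray]:
    """Measured pair (and any prior-model pair) plus seeded uniform fill to n."""
    lb, ub = (np.asarray(b, dtype=float) for b in problem_bounds)
    starts: list[np.ndarray] = []
    if measured_x is not None:
        starts.append(np.clip(np.asarray(measured_x, dtype=float), lb, ub))
    starts.extend(np.clip(np.asarray(e, dtype=float), lb, ub) for e in extra)
    rng = np.random.default_rng(seed)
    while len(starts) < n:
        starts.append(rng.uniform(lb, ub))
    return starts[:n]


def multi_start_fit(problem: OptProblem, refine: bool = True) -> list[Candidate]:
    """SA then Hooke-Jeeves from every start; candidates sorted by objective.

    Raises RuntimeError with diagnostics when no start yields a feasible
    candidate.  Identical seeds yield bit-identical candidate lists.
    """
    starts = problem.x0_list or tuple(
        make_start_points((problem.lb, problem.ub), problem.measured_x, 26, problem.seed)
    )
    seeds = np.random.SeedSequence(problem.seed).generate_state(len(starts))
    candidates = []
    for x0, sk in zip(starts, seeds):
        cand = simulated_annealing(problem, x0, seed=int(sk) % (2**31))
        if refine:
            refined = hooke_jeeves(problem, cand.x)
            if refined.f_value <= cand.f_value:
                cand = Candidate(
                    refined.x,
                    refined.f_value,
                    refined.g_value,
                    refined.delta_r,
                    refined.curvature_radius,
                    refined.feasible,
                    cand.n_evals + refined.n_evals,
                )
        candidates.append(cand)
    candidates.sort(key=lambda c: (not c.feasible, c.f_value))
    if not any(c.feasible for c in candidates):
        gmin = min(c.g_value for c in candidates)
        raise RuntimeError(
            f"all {len(candidates)} starts infeasible: min g = {gmin:.3f} mm "
            f"> epsilon = {problem.epsilon} mm"
        )
    return candidates


def radius_of_curvature(p1, p2, p3) -> float:
    """Circumradius (mm) of three successive attachment points.

    Collinear points give infinity (the smoothest possible path);
    coincident points are an error.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    if min(a, b, c) < 1e-12:
        raise ValueError("coincident points have no radius of curvature")
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
    if area < 1e-12 * a * b * c:
        return float("inf")
    return float(a * b * c / (4.0 * area))


def path_curvature_radius(chain: FingerChain, path: MusclePath, q: Posture = ZERO_POSTURE) -> float:
    """Smoothness of a tendon path: the smallest circumradius over successive
    attachment triples (world frame, wraps ignored).  Infinite for <3 points."""
    pts = resolve_path(chain, q, path, wraps=None).points
    if len(pts) < 3:
        return float("inf")
    radii = []
    for i in range(len(pts) - 2):
        try:
            radii.append(radius_of_curvature(pts[i], pts[i + 1], pts[i + 2]))
        except ValueError:
            continue
    return float(min(radii)) if radii else float("inf")


def select_candidate(
    candidates: Sequence[Candidate],
    measured_x: np.ndarray | None = None,
    middle_phalanx_length: float = 25.10,
) -> Candidate:
    """Anatomical selection rule among local minima.

    Among feasible candidates within 28% of the middle-phalanx length of the
    measured pair, pick the smoothest path (largest curvature radius); if
    none is that close, pick the one nearest the measured pair.  Ties fall
    back to the objective value.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    pool = [c for c in candidates if c.feasible] or list(candidates)
    if measured_x is not None:
        mx = np.asarray(measured_x, dtype=float)
        deltas = [
            max(
                float(np.linalg.norm(c.x[:3] - mx[:3])),
                float(np.linalg.norm(c.x[3:] - mx[3:])),
            )
            for c in pool
        ]
    else:
        deltas = [c.delta_r for c in pool]
        if any(math.isnan(d) for d in deltas):
            raise ValueError("candidates carry no measured-pair distance")
    threshold = 0.28 * middle_phalanx_length
    close = [(c, d) for c, d in zip(pool, deltas) if d <= threshold]
    if close:
        return max(close, key=lambda cd: (cd[0].curvature_radius, -cd[0].f_value))[0]
    return min(zip(pool, deltas), key=lambda cd: (cd[1], cd[0].f_value))[0]
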