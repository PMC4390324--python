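"""Muscle-tendon paths, cylinder wrapping, and moment arms.

A muscle path is an ordered list of attachment pairs, one pair per joint it
crosses, each point given in the local frame of the segment it rides on.
Between the two points of a pair the tendon runs straight unless it would
cut inside that joint's wrap cylinder, in which case the shortest route
around the cylinder (tangent - arc - tangent) is substituted.

Moment arms are computed two ways:

* ``partial_velocity`` -- the dot product of unit tension directions with
  the partial velocities of the path points with respect to the generalized
  coordinate; contact points on a wrap cylinder move rigidly with the bone
  the cylinder is fixed to (the sliding terms vanish for a shortest path).
* ``excursion_fd`` -- central finite difference of muscle-tendon length,
  ``-(L(q+h) - L(q-h)) / 2h`` with h = 1e-4 rad.

The two agree to better than 1e-6 mm away from wrap-engagement transitions,
which is the standard consistency check between the partial-velocity and
tendon-excursion definitions of a moment arm.

Sign convention: positive moment arm = flexion (the muscle shortens as the
joint flexes) or abduction; extensors come out negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .kinematics import (
    FingerChain,
    Posture,
    ZERO_POSTURE,
    posture_grid,
    segment_world_transforms,
)

__all__ = [
    "AttachmentPoint",
    "CrossingPair",
    "MusclePath",
    "WrapCylinder",
    "MomentArmCurve",
    "ResolvedPath",
    "MUSCLES",
    "EXTRINSIC",
    "INTRINSIC",
    "EXTENSOR_BANDS",
    "FLEXORS",
    "muscle_class",
    "epsilon_for",
    "wrap_side_for",
    "default_wrap_set",
    "resolve_path",
    "path_points_world",
    "path_length",
    "moment_arm",
    "moment_arm_curve",
    "mean_moment_arm",
    "scale_path",
    "scale_wraps",
]

EXTRINSIC = frozenset({"FDP", "FDS", "EDC"})
INTRINSIC = frozenset({"RI", "UI", "LU"})
EXTENSOR_BANDS = frozenset({"TE", "ES", "RB", "UB"})
MUSCLES = tuple(sorted(EXTRINSIC | INTRINSIC | EXTENSOR_BANDS))
#: Muscles routed on the palmar side of the joints they cross.
FLEXORS = frozenset({"FDP", "FDS", "RI", "UI", "LU"})

#: Index-finger joint dorsopalmar thickness (mm) from the packaged
#: anthropometry table; used to size default wrap cylinders.
_JOINT_THICKNESS_INDEX = {"MCP": 17.08, "PIP": 7.31, "DIP": 4.95}
_INDEX_PROXIMAL_LENGTH = 42.60

#: Default wrap radius as a fraction of joint thickness.  A quarter of the
#: dorsopalmar joint thickness approximates the bone radius at the neck where
#: tendons actually ride; half the head thickness would swallow several of
#: the packaged intrinsic-muscle attachment points.
DEFAULT_RADIUS_SCALE = 0.25


def muscle_class(muscle: str) -> str:
    if muscle in EXTRINSIC:
        return "extrinsic"
    if muscle in INTRINSIC:
        return "intrinsic"
    if muscle in EXTENSOR_BANDS:
        return "band"
    raise ValueError(f"unknown muscle {muscle!r}")


def epsilon_for(muscle: str) -> float:
    """Ab/adduction constraint tolerance: 2.5 mm extrinsic, 1.7 mm intrinsic."""
    return 2.5 if muscle_class(muscle) == "extrinsic" else 1.7


def wrap_side_for(muscle: str) -> str:
    return "palmar" if muscle in FLEXORS else "dorsal"


@dataclass(frozen=True)
class AttachmentPoint:
    segment: str
    coords: tuple[float, float, float]  # mm, segment-local

    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class CrossingPair:
    """Proximal/distal attachment pair straddling one joint."""

    joint: str
    proximal: AttachmentPoint
    distal: AttachmentPoint


@dataclass(frozen=True)
class MusclePath:
    muscle: str
    finger: int
    pairs: tuple[CrossingPair, ...]

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}")
        if not self.pairs:
            raise ValueError("muscle path needs at least one crossing pair")

    @property
    def muscle_class(self) -> str:
        return muscle_class(self.muscle)

    def joints(self) -> tuple[str, ...]:
        return tuple(p.joint for p in self.pairs)

    def pair_for(self, joint: str) -> CrossingPair:
        for p in self.pairs:
            if p.joint == joint:
                return p
        raise ValueError(f"muscle {self.muscle} does not cross joint {joint!r}")

    def with_pair(self, joint: str, proximal_xyz, distal_xyz) -> "MusclePath":
        """Copy with the pair at ``joint`` replaced by new coordinates."""
        pairs = []
        for p in self.pairs:
            if p.joint == joint:
                p = CrossingPair(
                    joint,
                    AttachmentPoint(p.proximal.segment, tuple(float(v) for v in proximal_xyz)),
                    AttachmentPoint(p.distal.segment, tuple(float(v) for v in distal_xyz)),
                )
            pairs.append(p)
        return replace(self, pairs=tuple(pairs))


@dataclass(frozen=True)
class WrapCylinder:
    """Wrap obstacle along the flexion axis through a joint centre.

    The cylinder is fixed to the joint's parent segment; ``side`` is the side
    the tendon is routed around when the straight segment would penetrate.
    """

    joint: str
    radius: float  # mm
    side: str  # "palmar" | "dorsal"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("wrap radius must be > 0")
        if self.side not in ("palmar", "dorsal"):
            raise ValueError(f"side must be palmar or dorsal, got {self.side!r}")


def default_wrap_set(
    chain: FingerChain,
    muscle: str,
    radius_scale: float = DEFAULT_RADIUS_SCALE,
    thickness: Mapping[str, float] | None = None,
) -> dict[str, WrapCylinder]:
    """One cylinder per joint sized from joint thickness, scaled isometrically.

    Joint thickness is tabulated for the index finger; other fingers scale it
    by the ratio of proximal phalanx lengths.
    """
    side = wrap_side_for(muscle)
    if thickness is None:
        s = chain.segment("proximal").length / _INDEX_PROXIMAL_LENGTH
        thickness = {k: v * s for k, v in _JOINT_THICKNESS_INDEX.items()}
    return {
        j.name: WrapCylinder(j.name, radius_scale * thickness[j.name], side)
        for j in chain.joints
        if j.name in thickness
    }


@dataclass(frozen=True)
class MomentArmCurve:
    joint: str
    dof: str
    angles: np.ndarray  # degrees, strictly increasing
    values: np.ndarray  # mm, signed
    source: str = "model"  # measured | derived | model
    muscle: str | None = None
    finger: int | None = None
    reference: float | None = None  # normalization reference, if any

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "values", v)
        if a.size != v.size:
            raise ValueError("angles and values must have equal length")
        if a.size and not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("moment arm values must be finite")


# ---------------------------------------------------------------------------
# path resolution


@dataclass
class _Arc:
    i0: int
    i1: int
    radius: float
    sweep: float  # rad, > 0
    axis: np.ndarray  # world unit vector

    def length(self, points: Sequence[np.ndarray]) -> float:
        axial = float(self.axis @ (points[self.i1] - points[self.i0]))
        return math.hypot(self.radius * self.sweep, axial)


@dataclass
class ResolvedPath:
    """World-frame polyline of a muscle path at one posture.

    ``points[i]`` rides on segment index ``bodies[i]``; ``elements`` is the
    ordered mix of straight lines and cylinder arcs joining them.
    """

    points: list[np.ndarray]
    bodies: list[int]
    elements: list[tuple]  # ("line", i0, i1) | ("arc", _Arc)

    def length(self) -> float:
        total = 0.0
        for el in self.elements:
            if el[0] == "line":
                total += float(np.linalg.norm(self.points[el[2]] - self.points[el[1]]))
            else:
                total += el[1].length(self.points)
        return total


def _solve_wrap_2d(pu, pv, du, dv, radius, side):
    """Tangent-arc-tangent geometry in the plane perpendicular to the axis.

    The pair wraps when the straight chord penetrates the cylinder (closest
    approach to the axis < radius, with the crossing between the endpoints);
    the path is then routed around the configured side, which also restores
    a palmar pulley for chords that graze marginally dorsal of the axis.
    Returns None when the pair does not wrap, else
    (phi1, phi2, sweep, t_p, t_d, direction) with sweep > 0.
    """
    dp = math.hypot(pu, pv)
    dd = math.hypot(du, dv)
    if dp <= radius or dd <= radius:
        return None  # endpoint inside the cylinder: treat as straight
    eu, ev = du - pu, dv - pv
    elen = math.hypot(eu, ev)
    if elen < 1e-12:
        return None
    if abs(pu * dv - pv * du) / elen >= radius:
        return None  # chord clears the cylinder
    t_foot = -(pu * eu + pv * ev) / (elen * elen)
    if not 0.0 < t_foot < 1.0:
        return None  # closest approach outside the chord
    th_p = math.atan2(pv, pu)
    th_d = math.atan2(dv, du)
    delta_ccw = (th_d - th_p) % (2.0 * math.pi)
    side_angle = -0.5 * math.pi if side == "palmar" else 0.5 * math.pi
    passes_ccw = ((side_angle - th_p) % (2.0 * math.pi)) <= delta_ccw
    delta = delta_ccw if passes_ccw else delta_ccw - 2.0 * math.pi
    beta_p = math.acos(radius / dp)
    beta_d = math.acos(radius / dd)
    sweep = abs(delta) - beta_p - beta_d
    if sweep <= 0.0:
        return None  # tangents overlap: no arc on this side
    direction = 1.0 if delta > 0 else -1.0
    phi1 = th_p + direction * beta_p
    phi2 = th_d - direction * beta_d
    t_p = math.sqrt(dp * dp - radius * radius)
    t_d = math.sqrt(dd * dd - radius * radius)
    return phi1, phi2, sweep, t_p, t_d, direction


def resolve_path(
    chain: FingerChain,
    q: Posture,
    path: MusclePath,
    wraps: Mapping[str, WrapCylinder] | None = None,
) -> ResolvedPath:
    """Resolve attachment points (and wrap contact points) to world coordinates."""
    poses = segment_world_transforms(chain, q)
    points: list[np.ndarray] = []
    bodies: list[int] = []
    elements: list[tuple] = []

    def add_point(pt: np.ndarray, body: int) -> int:
        points.append(pt)
        bodies.append(body)
        return len(points) - 1

    prev_idx: int | None = None
    for pair in path.pairs:
        ji = chain.joint_index(pair.joint)
        ip = chain.segment_index(pair.proximal.segment)
        idist = chain.segment_index(pair.distal.segment)
        rp, tp = poses[ip]
        rd, td = poses[idist]
        p_w = rp @ pair.proximal.xyz() + tp
        d_w = rd @ pair.distal.xyz() + td
        i_p = add_point(p_w, ip)
        if prev_idx is not None:
            elements.append(("line", prev_idx, i_p))

        wrap = (wraps or {}).get(pair.joint)
        handled = False
        if wrap is not None:
            r_par, t_par = poses[ji]
            centre = t_par + r_par @ np.array([0.0, -chain.joint_offset(ji), 0.0])
            axis = r_par[:, 0]  # parent x: the flexion axis direction
            u_hat, v_hat = r_par[:, 1], r_par[:, 2]  # (y, z): v > 0 dorsal
            rel_p, rel_d = p_w - centre, d_w - centre
            sol = _solve_wrap_2d(
                rel_p @ u_hat, rel_p @ v_hat, rel_d @ u_hat, rel_d @ v_hat, wrap.radius, wrap.side
            )
            if sol is not None:
                phi1, phi2, sweep, t_p, t_d, _ = sol
                lp = t_p + wrap.radius * sweep + t_d
                ax_p = float(rel_p @ axis)
                h = float(rel_d @ axis) - ax_p
                ax1 = ax_p + h * (t_p / lp)
                ax2 = ax_p + h * ((t_p + wrap.radius * sweep) / lp)
                c1 = centre + wrap.radius * (math.cos(phi1) * u_hat + math.sin(phi1) * v_hat) + ax1 * axis
                c2 = centre + wrap.radius * (math.cos(phi2) * u_hat + math.sin(phi2) * v_hat) + ax2 * axis
                i_c1 = add_point(c1, ji)  # contacts ride on the parent bone
                i_c2 = add_point(c2, ji)
                i_d = add_point(d_w, idist)
                elements.append(("line", i_p, i_c1))
                elements.append(("arc", _Arc(i_c1, i_c2, wrap.radius, sweep, axis)))
                elements.append(("line", i_c2, i_d))
                handled = True
        if not handled:
            i_d = add_point(d_w, idist)
            elements.append(("line", i_p, i_d))
        prev_idx = i_d
    return ResolvedPath(points, bodies, elements)


def path_points_world(
    chain: FingerChain,
    q: Posture,
    path: MusclePath,
    wraps: Mapping[str, WrapCylinder] | None = None,
) -> list[np.ndarray]:
    """Ordered proximal-to-distal world points, wrap contact points included."""
    return resolve_path(chain, q, path, wraps).points


def path_length(
    chain: FingerChain,
    q: Posture,
    path: MusclePath,
    wraps: Mapping[str, WrapCylinder] | None = None,
) -> float:
    """Muscle-tendon length (mm): straight segments plus geodesic arc lengths."""
    return resolve_path(chain, q, path, wraps).length()


# ---------------------------------------------------------------------------
# moment arms


def _dof_axis_and_centre(chain: FingerChain, q: Posture, poses, joint: str, dof: str):
    ji = chain.joint_index(joint)
    spec = chain.joint(joint)
    r_par, t_par = poses[ji]
    centre = t_par + r_par @ np.array([0.0, -chain.joint_offset(ji), 0.0])
    rot = np.eye(3)
    for d in spec.dofs:
        if d.name == dof:
            local = np.array([1.0, 0.0, 0.0]) if d.axis == "x" else np.array([0.0, 0.0, 1.0])
            return r_par @ rot @ local, centre, ji
        ang = math.radians(q.angle(joint, d.name))
        c, s = math.cos(ang), math.sin(ang)
        step = (
            np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            if d.axis == "z"
            else np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        )
        rot = rot @ step
    raise KeyError(f"joint {joint} has no dof {dof!r}")


def _partial_velocity_ma(chain, q, path, joint, dof, wraps) -> float:
    poses = segment_world_transforms(chain, q)
    axis, centre, ji = _dof_axis_and_centre(chain, q, poses, joint, dof)
    rp = resolve_path(chain, q, path, wraps)

    def vel(idx: int) -> np.ndarray:
        if rp.bodies[idx] >= ji + 1:
            return np.cross(axis, rp.points[idx] - centre)
        return np.zeros(3)

    dl = 0.0
    for el in rp.elements:
        if el[0] != "line":
            continue  # arcs are rigid with their bone: zero length change
        a, b = rp.points[el[1]], rp.points[el[2]]
        seg = b - a
        norm = float(np.linalg.norm(seg))
        if norm < 1e-12:
            continue
        dl += float(seg @ (vel(el[2]) - vel(el[1]))) / norm
    return -dl


def _excursion_fd_ma(chain, q, path, joint, dof, wraps, h: float) -> float:
    dh = math.degrees(h)
    a0 = q.angle(joint, dof)
    lp = path_length(chain, q.replace(joint, dof, a0 + dh), path, wraps)
    lm = path_length(chain, q.replace(joint, dof, a0 - dh), path, wraps)
    return -(lp - lm) / (2.0 * h)


def moment_arm(
    chain: FingerChain,
    q: Posture,
    path: MusclePath,
    joint: str,
    dof: str = "flexion",
    method: str = "partial_velocity",
    wraps: Mapping[str, WrapCylinder] | None = None,
    h: float = 1e-4,
    strict: bool = True,
    validate: bool = False,
) -> float:
    """Moment arm (mm) of ``path`` about one joint DOF at posture ``q``.

    ``strict`` errors when the path has no pair crossing the joint (the
    physical moment arm there is zero).  With ``validate`` the two methods
    are cross-checked and a warning is issued if they disagree by more than
    0.01 mm, which flags a wrap-engagement transition.
    """
    if strict and joint not in path.joints():
        raise ValueError(f"muscle {path.muscle} does not cross joint {joint!r}")
    chain.joint(joint).dof(dof)  # raises KeyError for an unknown dof
    pv = _partial_velocity_ma(chain, q, path, joint, dof, wraps)
    if method == "partial_velocity":
        result = pv
    elif method == "excursion_fd":
        result = _excursion_fd_ma(chain, q, path, joint, dof, wraps, h)
    else:
        raise ValueError(f"unknown method {method!r}")
    if validate:
        fd = _excursion_fd_ma(chain, q, path, joint, dof, wraps, h)
        if abs(pv - fd) > 0.01:
            warnings.warn(
                f"moment arm methods disagree by {abs(pv - fd):.3g} mm at "
                f"{joint}/{dof} (wrap transition?)",
                RuntimeWarning,
                stacklevel=2,
            )
    return result


def moment_arm_curve(
    chain: FingerChain,
    path: MusclePath,
    joint: str,
    dof: str = "flexion",
    m: int = 100,
    wraps: Mapping[str, WrapCylinder] | None = None,
    reference: Posture = ZERO_POSTURE,
    method: str = "partial_velocity",
) -> MomentArmCurve:
    """Moment arm sampled on an ``m``-point grid covering the DOF's RoM."""
    angles, postures = posture_grid(chain, joint, dof, m, reference)
    values = np.array(
        [moment_arm(chain, qi, path, joint, dof, method=method, wraps=wraps) for qi in postures]
    )
    return MomentArmCurve(
        joint, dof, angles, values, source="model", muscle=path.muscle, finger=path.finger
    )


def mean_moment_arm(curve: MomentArmCurve) -> float:
    """Arithmetic mean of the signed moment arm over the grid."""
    if curve.values.size == 0:
        raise ValueError("cannot average an empty moment arm curve")
    return float(np.mean(curve.values))


# ---------------------------------------------------------------------------
# isometric scaling helpers


def scale_path(path: MusclePath, s: float) -> MusclePath:
    pairs = tuple(
        CrossingPair(
            p.joint,
            AttachmentPoint(p.proximal.segment, tuple(s * v for v in p.proximal.coords)),
            AttachmentPoint(p.distal.segment, tuple(s * v for v in p.distal.coords)),
        )
        for p in path.pairs
    )
    return replace(path, pairs=pairs)


def scale_wraps(wraps: Mapping[str, WrapCylinder], s: float) -> dict[str, WrapCylinder]:
    return {k: WrapCylinder(w.joint, w.radius * s, w.side) for k, w in wraps.items()}
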