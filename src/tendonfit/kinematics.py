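"""Finger kinematic chains and rigid-frame transforms.

Each finger (index=2 .. little=5) is a serial chain of four bone segments --
metacarpal, proximal, middle and distal phalanx -- linked by three joints:

* MCP (metacarpophalangeal): universal joint, ab/adduction about the local
  z axis followed by flexion about the rotated x axis,
* PIP / DIP (interphalangeal): revolute flexion joints about the local x axis.

Frame convention (right-handed, millimetres): +x radial along the flexion
axis, +y proximal along the bone long axis, +z dorsal.  Each phalanx frame
has its origin at the proximal joint centre of that bone (proximal phalanx
frame at the MCP centre, middle at PIP, distal at DIP).  The metacarpal
frame sits mid-metacarpal; the MCP centre lies at ``y = -metacarpal_frame_offset``.

Joint ranges of motion: MCP flexion 0-90 deg and ab/adduction 0-30 deg,
PIP flexion 0-90 deg, DIP flexion 0-50 deg; 0 deg is full extension with
flexion positive (palmar) and abduction positive (radial).

All public interfaces take angles in degrees; radians are used internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SegmentSpec",
    "DofSpec",
    "JointSpec",
    "FingerChain",
    "Posture",
    "ZERO_POSTURE",
    "DEFAULT_DIMENSIONS",
    "DEFAULT_METACARPAL_OFFSETS",
    "build_finger_chain",
    "frame_transform",
    "posture_grid",
    "validate_posture",
    "chain_to_json",
    "chain_from_json",
]

SEGMENT_ORDER = ("metacarpal", "proximal", "middle", "distal")
JOINT_ORDER = ("MCP", "PIP", "DIP")

#: Index-finger phalanx lengths from the packaged anthropometry table; the
#: other fingers use generic 50th-percentile proportions consistent with the
#: packaged attachment tables (the source prints bony dimensions only for the
#: index finger).  Override by passing an explicit ``dims`` mapping.
DEFAULT_DIMENSIONS: dict[int, dict[str, float]] = {
    2: {"proximal": 42.60, "middle": 25.10, "distal": 19.10},
    3: {"proximal": 44.80, "middle": 29.00, "distal": 20.50},
    4: {"proximal": 41.50, "middle": 24.00, "distal": 19.00},
    5: {"proximal": 34.00, "middle": 20.00, "distal": 17.00},
}

#: Placeholder distance (mm) from the mid-metacarpal frame origin to the MCP
#: centre along -y (half a generic metacarpal bone length).  Config value;
#: not derivable from the packaged tables.
DEFAULT_METACARPAL_OFFSETS: dict[int, float] = {2: 34.0, 3: 32.0, 4: 29.0, 5: 27.0}


class ValidationError(ValueError):
    """Raised for inconsistent chain definitions or postures."""


@dataclass(frozen=True)
class SegmentSpec:
    name: str
    length: float  # mm

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValidationError(f"segment {self.name!r}: length must be > 0, got {self.length}")


@dataclass(frozen=True)
class DofSpec:
    name: str  # "flexion" | "abduction"
    axis: str  # "x" | "z"
    rom_deg: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.rom_deg
        if not lo < hi:
            raise ValidationError(f"dof {self.name!r}: RoM lo must be < hi, got {self.rom_deg}")


@dataclass(frozen=True)
class JointSpec:
    name: str  # "MCP" | "PIP" | "DIP"
    kind: str  # "universal" | "revolute"
    dofs: tuple[DofSpec, ...]

    def dof(self, name: str) -> DofSpec:
        for d in self.dofs:
            if d.name == name:
                return d
        raise KeyError(f"joint {self.name} has no dof {name!r}")

    @property
    def dof_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dofs)


def _default_joints() -> tuple[JointSpec, ...]:
    return (
        JointSpec(
            "MCP",
            "universal",
            (
                DofSpec("abduction", "z", (0.0, 30.0)),
                DofSpec("flexion", "x", (0.0, 90.0)),
            ),
        ),
        JointSpec("PIP", "revolute", (DofSpec("flexion", "x", (0.0, 90.0)),)),
        JointSpec("DIP", "revolute", (DofSpec("flexion", "x", (0.0, 50.0)),)),
    )


@dataclass(frozen=True)
class FingerChain:
    """Four segments, three joints; joint i connects segment i to segment i+1."""

    finger: int
    segments: tuple[SegmentSpec, ...]
    joints: tuple[JointSpec, ...]
    metacarpal_frame_offset: float  # mm, mid-metacarpal origin to MCP centre

    def __post_init__(self) -> None:
        if len(self.segments) != 4 or len(self.joints) != 3:
            raise ValidationError("chain needs 4 segments and 3 joints")
        names = [s.name for s in self.segments]
        if len(set(names)) != 4:
            raise ValidationError(f"segment names not unique: {names}")
        if self.metacarpal_frame_offset <= 0:
            raise ValidationError("metacarpal_frame_offset must be > 0")

    def segment_index(self, name: str) -> int:
        for i, s in enumerate(self.segments):
            if s.name == name:
                return i
        raise KeyError(f"unknown segment {name!r} (chain has {[s.name for s in self.segments]})")

    def joint_index(self, name: str) -> int:
        for i, j in enumerate(self.joints):
            if j.name == name:
                return i
        raise KeyError(f"unknown joint {name!r}")

    def joint(self, name: str) -> JointSpec:
        return self.joints[self.joint_index(name)]

    def segment(self, name: str) -> SegmentSpec:
        return self.segments[self.segment_index(name)]

    def joint_offset(self, joint_index: int) -> float:
        """Distance along -y from the parent frame origin to the joint centre."""
        if joint_index == 0:
            return self.metacarpal_frame_offset
        return self.segments[joint_index].length

    def scaled(self, s: float) -> "FingerChain":
        """All linear dimensions scaled isometrically by ``s`` (> 0)."""
        if s <= 0:
            raise ValidationError("scale factor must be > 0")
        return FingerChain(
            self.finger,
            tuple(SegmentSpec(seg.name, seg.length * s) for seg in self.segments),
            self.joints,
            self.metacarpal_frame_offset * s,
        )


@dataclass(frozen=True)
class Posture:
    """Joint angles in degrees keyed by (joint name, dof name); absent = 0."""

    angles: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def angle(self, joint: str, dof: str) -> float:
        return float(self.angles.get((joint, dof), 0.0))

    def replace(self, joint: str, dof: str, value: float) -> "Posture":
        d = dict(self.angles)
        d[(joint, dof)] = value
        return Posture(d)


ZERO_POSTURE = Posture({})


def build_finger_chain(
    dims: Mapping[str, float] | None = None,
    finger: int = 2,
    metacarpal_frame_offset: float | None = None,
) -> FingerChain:
    """Build the finger chain from a phalanx-length table.

    ``dims`` maps ``proximal | middle | distal`` to lengths in mm (missing or
    non-positive entries raise :class:`ValidationError` naming the field).
    When omitted, packaged per-finger defaults are used.
    """
    if finger not in (2, 3, 4, 5):
        raise ValidationError(f"finger must be 2-5, got {finger}")
    if dims is None:
        dims = DEFAULT_DIMENSIONS[finger]
    lengths = {}
    for name in ("proximal", "middle", "distal"):
        if name not in dims:
            raise ValidationError(f"missing dimension: {name!r}")
        val = float(dims[name])
        if not val > 0:
            raise ValidationError(f"dimension {name!r} must be > 0, got {val}")
        lengths[name] = val
    offset = metacarpal_frame_offset
    if offset is None:
        offset = float(dims.get("metacarpal_frame_offset", DEFAULT_METACARPAL_OFFSETS[finger]))
    segments = (
        SegmentSpec("metacarpal", 2.0 * offset),
        SegmentSpec("proximal", lengths["proximal"]),
        SegmentSpec("middle", lengths["middle"]),
        SegmentSpec("distal", lengths["distal"]),
    )
    return FingerChain(finger, segments, _default_joints(), offset)


def _rot_x(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def joint_rotation(joint: JointSpec, q: Posture) -> np.ndarray:
    """Child-to-parent rotation at one joint (ab/adduction about z, then flexion about x)."""
    rot = np.eye(3)
    for dof in joint.dofs:  # declaration order: abduction (z) then flexion (x)
        ang = math.radians(q.angle(joint.name, dof.name))
        rot = rot @ (_rot_z(ang) if dof.axis == "z" else _rot_x(ang))
    return rot


def segment_world_transforms(chain: FingerChain, q: Posture) -> list[tuple[np.ndarray, np.ndarray]]:
    """World (= metacarpal-frame) pose (R, t) of every segment frame."""
    poses = [(np.eye(3), np.zeros(3))]
    for i, joint in enumerate(chain.joints):
        r_parent, t_parent = poses[-1]
        centre_local = np.array([0.0, -chain.joint_offset(i), 0.0])
        r = r_parent @ joint_rotation(joint, q)
        t = t_parent + r_parent @ centre_local
        poses.append((r, t))
    return poses


def frame_transform(
    chain: FingerChain, q: Posture, frm: str, to: str
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) mapping coordinates in segment ``frm`` to segment ``to``.

    ``p_to = R @ p_frm + t``.  Exact inverse when the arguments are swapped.
    """
    poses = segment_world_transforms(chain, q)
    r_f, t_f = poses[chain.segment_index(frm)]
    r_t, t_t = poses[chain.segment_index(to)]
    r = r_t.T @ r_f
    t = r_t.T @ (t_f - t_t)
    return r, t


def posture_grid(
    chain: FingerChain,
    joint: str,
    dof: str = "flexion",
    m: int = 100,
    reference: Posture = ZERO_POSTURE,
) -> tuple[np.ndarray, list[Posture]]:
    """``m`` evenly spaced postures sweeping one DOF over its full RoM.

    Returns the swept angles (degrees) and the posture list; all other DOFs
    stay at the reference posture (default 0 deg everywhere).
    """
    if m < 2:
        raise ValidationError(f"grid size m must be >= 2, got {m}")
    spec = chain.joint(joint).dof(dof)
    angles = np.linspace(spec.rom_deg[0], spec.rom_deg[1], m)
    return angles, [reference.replace(joint, dof, float(a)) for a in angles]


def validate_posture(chain: FingerChain, q: Posture) -> list[str]:
    """Out-of-range angles as human-readable violation strings (empty = valid)."""
    violations = []
    for (joint_name, dof_name), value in q.angles.items():
        try:
            spec = chain.joint(joint_name).dof(dof_name)
        except KeyError:
            violations.append(f"unknown dof {joint_name}/{dof_name}")
            continue
        lo, hi = spec.rom_deg
        if not (lo <= value <= hi):
            violations.append(
                f"{joint_name} {dof_name} = {value:g} deg outside RoM [{lo:g}, {hi:g}]"
            )
    return violations


def chain_to_json(chain: FingerChain) -> str:
    doc = {
        "finger": chain.finger,
        "segments": [{"name": s.name, "length_mm": s.length} for s in chain.segments],
        "joints": [
            {
                "name": j.name,
                "kind": j.kind,
                "dofs": [
                    {"name": d.name, "axis": d.axis, "rom_deg": list(d.rom_deg)} for d in j.dofs
                ],
            }
            for j in chain.joints
        ],
        "metacarpal_frame_offset_mm": chain.metacarpal_frame_offset,
    }
    return json.dumps(doc, indent=2)


def chain_from_json(text: str) -> FingerChain:
    doc = json.loads(text)
    return FingerChain(
        int(doc["finger"]),
        tuple(SegmentSpec(s["name"], float(s["length_mm"])) for s in doc["segments"]),
        tuple(
            JointSpec(
                j["name"],
                j["kind"],
                tuple(
                    DofSpec(d["name"], d["axis"], (float(d["rom_deg"][0]), float(d["rom_deg"][1])))
                    for d in j["dofs"]
                ),
            )
            for j in doc["joints"]
        ),
        float(doc["metacarpal_frame_offset_mm"]),
    )
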