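"""Frame mapping, isometric scaling, normalization and skin bounds.

Source-study attachment coordinates are measured in per-bone reference
frames that differ from the model segment frames in origin, orientation and
scale.  They are brought across in two steps: an isometric scale (model
dimension over specimen dimension) followed by a rigid transform built from
four Denavit-Hartenberg-style parameters -- segment rotation theta, segment
distance d, joint twist alpha and joint offset a.

The fixed frame correspondence: source frames 2, 4, 6 (bone-head centres of
rotation) map to the model PIP, MCP and mid-metacarpal frames; source
frames 1, 3, 5 (concave articular-surface centres) map to the model DIP,
PIP and MCP frames.

The skin surface, scaled in three dimensions from the bony segments, bounds
how far an optimized attachment may sit from the bone; it is modelled as an
axis-aligned box around each segment's long axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinematics import FingerChain
from .musclepath import MomentArmCurve

__all__ = [
    "SOURCE_FRAME_TARGETS",
    "TransformParams",
    "ScaleSet",
    "BoundBox",
    "build_transform",
    "apply_transform",
    "invert_transform",
    "map_attachment",
    "normalize_moment_arm",
    "denormalize_moment_arm",
    "skin_bounds",
    "scale_set_from_table",
]

SOURCE_FRAME_TARGETS = {
    1: "DIP",
    2: "PIP",
    3: "PIP",
    4: "MCP",
    5: "MCP",
    6: "mid-metacarpal",
}


@dataclass(frozen=True)
class TransformParams:
    """(theta, d, alpha, a) rigid-transform parameters for one source frame."""

    theta_deg: float = 0.0  # segment rotation about z
    d: float = 0.0  # segment distance along z, mm
    alpha_deg: float = 0.0  # joint twist about x
    a: float = 0.0  # joint offset along x, mm
    source_frame: int = 4
    target_frame: str = "MCP"

    def __post_init__(self) -> None:
        if self.source_frame not in SOURCE_FRAME_TARGETS:
            raise KeyError(
                f"unmapped source frame {self.source_frame}; known: "
                f"{sorted(SOURCE_FRAME_TARGETS)}"
            )


def build_transform(p: TransformParams) -> np.ndarray:
    """Homogeneous 4x4 transform Rz(theta) Tz(d) Tx(a) Rx(alpha)."""
    th = math.radians(p.theta_deg)
    al = math.radians(p.alpha_deg)
    ct, st = math.cos(th), math.sin(th)
    ca, sa = math.cos(al), math.sin(al)
    return np.array(
        [
            [ct, -st * ca, st * sa, p.a * ct],
            [st, ct * ca, -ct * sa, p.a * st],
            [0.0, sa, ca, p.d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def apply_transform(t: np.ndarray, point) -> np.ndarray:
    point = np.asarray(point, dtype=float)
    return t[:3, :3] @ point + t[:3, 3]


def invert_transform(t: np.ndarray) -> np.ndarray:
    out = np.eye(4)
    out[:3, :3] = t[:3, :3].T
    out[:3, 3] = -t[:3, :3].T @ t[:3, 3]
    return out


@dataclass(frozen=True)
class ScaleSet:
    """Per-dimension specimen, model and skin sizes (mm, all positive)."""

    specimen: dict[str, float]
    model: dict[str, float]
    skin: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (("specimen", self.specimen), ("model", self.model), ("skin", self.skin)):
            for k, v in table.items():
                if not v > 0:
                    raise ValueError(f"{name} dimension {k!r} must be > 0, got {v}")

    def ratio(self, dimension: str) -> float:
        """Model-over-specimen isometric scale factor for one dimension."""
        return self.model[dimension] / self.specimen[dimension]


def scale_set_from_table(table: pd.DataFrame) -> ScaleSet:
    """Build a ScaleSet from the packaged anthropometry table."""
    t = table.set_index("dimension")
    return ScaleSet(
        specimen=t["specimen_mm"].to_dict(),
        model=t["model_mm"].to_dict(),
        skin=t["skin_mm"].to_dict(),
    )


def map_attachment(point, p: TransformParams, scale: float | ScaleSet = 1.0,
                   dimension: str | None = None) -> np.ndarray:
    """Scale a source-frame point isometrically, then rigidly transform it.

    ``scale`` is either an explicit factor or a :class:`ScaleSet` together
    with the ``dimension`` whose model/specimen ratio applies.
    """
    if isinstance(scale, ScaleSet):
        if dimension is None:
            raise ValueError("dimension required when scaling from a ScaleSet")
        factor = scale.ratio(dimension)
    else:
        factor = float(scale)
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    return apply_transform(build_transform(p), factor * np.asarray(point, dtype=float))


def normalize_moment_arm(curve: MomentArmCurve, reference: float) -> MomentArmCurve:
    """Divide a moment-arm curve by a reference length (dimensionless result).

    The conventional references are the middle-phalanx length for PIP/DIP
    flexion curves, the MCP joint thickness for MCP flexion and the MCP
    width for ab/adduction.
    """
    if reference <= 0:
        raise ValueError(f"normalization reference must be > 0, got {reference}")
    return replace(curve, values=curve.values / reference, reference=reference)


def denormalize_moment_arm(curve: MomentArmCurve) -> MomentArmCurve:
    if curve.reference is None:
        raise ValueError("curve carries no normalization reference")
    return replace(curve, values=curve.values * curve.reference, reference=None)


@dataclass(frozen=True)
class BoundBox:
    """Axis-aligned box around a segment's long (y) axis, mm."""

    segment: str
    lb: tuple[float, float, float]
    ub: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(l < u for l, u in zip(self.lb, self.ub)):
            raise ValueError(f"degenerate bound box: lb={self.lb} ub={self.ub}")

    def contains(self, point, tol: float = 0.0) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= np.asarray(self.lb) - tol) and np.all(p <= np.asarray(self.ub) + tol))


_SEGMENT_BOUND_JOINT = {"metacarpal": "MCP", "proximal": "MCP", "middle": "PIP", "distal": "DIP"}


def skin_bounds(chain: FingerChain, scale: ScaleSet, segment: str, joint: str | None = None) -> BoundBox:
    """Skin-surface box for attachments on one segment.

    The dorsopalmar (z) half-extent is half the skin joint thickness at the
    governing joint; the radioulnar (x) half-extent reuses the same value
    because separate widths are not tabulated.  The box spans the segment
    along -y with a joint-thickness margin at each end.
    """
    idx = chain.segment_index(segment)
    if joint is None:
        joint = _SEGMENT_BOUND_JOINT[segment]
    key = f"{joint}_joint_thickness"
    if key not in scale.skin:
        raise KeyError(f"missing skin dimension {key!r}")
    half = scale.skin[key] / 2.0
    length = chain.metacarpal_frame_offset if idx == 0 else chain.segments[idx].length
    return BoundBox(segment, (-half, -length - half, -half), (half, half, half))
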