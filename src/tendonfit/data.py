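"""Packaged reference tables, CSV dialects and synthetic target generation.

Three reference tables ship with the package (verbatim from the source
study, checksum-verified at load time):

* ``anthropometry_index.csv`` -- index-finger phalanx lengths and joint
  thicknesses for cadaveric specimens, the model skeleton and the scaled
  skin surface (mm),
* ``attachments.csv`` -- optimized and measured muscle-tendon attachment
  coordinates for all four fingers, 13 muscle-joint pairs each, with the
  printed Euclidean distances where available,
* ``mean_moment_arms.csv`` -- mean moment arms (plus VAF/RMS) per
  finger x joint x DOF x muscle, used for sign and ordering regressions.

The attachment CSV dialect is strict: UTF-8, comma separated, ``.``
decimal point, mandatory header, no extra columns.

Synthetic moment-arm targets are produced by evaluating the model on known
("true") attachments and adding i.i.d. Gaussian noise -- the recovery
harness for the attachment optimizer when measured curves are unavailable.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .kinematics import FingerChain, posture_grid
from .musclepath import (
    AttachmentPoint,
    CrossingPair,
    MomentArmCurve,
    MusclePath,
    WrapCylinder,
    default_wrap_set,
    epsilon_for,
    moment_arm,
)
from .optimizer import HJSettings, OptProblem, SASchedule, make_start_points
from .transforms import ScaleSet, scale_set_from_table, skin_bounds

__all__ = [
    "FixtureSet",
    "SyntheticSpec",
    "load_fixtures",
    "index_scale_set",
    "read_attachment_csv",
    "write_attachment_csv",
    "read_curve_csv",
    "write_curve_csv",
    "muscle_path_from_table",
    "all_muscle_paths",
    "pair_vector",
    "bounds_for_pair",
    "make_problem",
    "generate_synthetic_targets",
]

_DATA_FILES = {
    "anthropometry_index.csv": "eaeb3973018fde1d84b104b61625e6248719748a409cc9fd31828e4da7641ed6",
    "attachments.csv": "ba9ef5b9c5dfeb2f8a0960f87f1b1f45ad9ae8c2128caf1fae902ba5a86d6458",
    "mean_moment_arms.csv": "531df64302724a01e7055fb70cb789bf81848e8a63f0217a7784cd8e01c1a1d3",
}

ATTACHMENT_COLUMNS = [
    "finger",
    "joint",
    "muscle",
    "point_role",
    "segment",
    "x_mm",
    "y_mm",
    "z_mm",
    "delta_r_mm",
    "source",
]
CURVE_COLUMNS = ["finger", "muscle", "joint", "dof", "angle_deg", "moment_arm_mm", "source"]

_JOINT_ORDER = {"MCP": 0, "PIP": 1, "DIP": 2}


def _read_packaged(name: str) -> str:
    text = resources.files("tendonfit.tables").joinpath(name).read_text(encoding="utf-8")
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if digest != _DATA_FILES[name]:
        raise RuntimeError(f"packaged table {name} is corrupted (sha256 {digest})")
    return text


@dataclass(frozen=True)
class FixtureSet:
    table1: pd.DataFrame  # anthropometry (index finger)
    attachments: pd.DataFrame  # optimized + measured coordinates, all fingers
    mean_ma: pd.DataFrame  # mean moment arms per finger/joint/dof/muscle


def load_fixtures() -> FixtureSet:
    """Load and checksum-verify the packaged reference tables."""
    table1 = pd.read_csv(io.StringIO(_read_packaged("anthropometry_index.csv")))
    attachments = pd.read_csv(io.StringIO(_read_packaged("attachments.csv")))
    mean_ma = pd.read_csv(io.StringIO(_read_packaged("mean_moment_arms.csv")))
    return FixtureSet(table1, attachments, mean_ma)


def index_scale_set(fixtures: FixtureSet | None = None) -> ScaleSet:
    fixtures = fixtures or load_fixtures()
    return scale_set_from_table(fixtures.table1)


# ---------------------------------------------------------------------------
# attachment / curve CSV dialects


def read_attachment_csv(path) -> pd.DataFrame:
    """Strict reader for the attachment-table dialect.

    Errors name the offending line; unknown or missing columns and
    non-'.'-decimal numbers are rejected.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, header row is mandatory") from None
        if header != ATTACHMENT_COLUMNS:
            unknown = set(header) - set(ATTACHMENT_COLUMNS)
            missing = set(ATTACHMENT_COLUMNS) - set(header)
            raise ValueError(
                f"{path}: bad header; unknown columns {sorted(unknown)}, "
                f"missing columns {sorted(missing)}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(ATTACHMENT_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(ATTACHMENT_COLUMNS)} fields, got "
                    f"{len(row)} (decimal commas are not a supported dialect)"
                )
            rec = dict(zip(ATTACHMENT_COLUMNS, row))
            try:
                rec["finger"] = int(rec["finger"])
                for col in ("x_mm", "y_mm", "z_mm"):
                    rec[col] = float(rec[col])
                rec["delta_r_mm"] = float(rec["delta_r_mm"]) if rec["delta_r_mm"] else np.nan
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number ({exc})") from None
            if rec["source"] not in ("optimized", "measured"):
                raise ValueError(f"{path}:{lineno}: bad source {rec['source']!r}")
            if rec["point_role"] not in ("proximal", "distal", "bound_min", "bound_max"):
                raise ValueError(f"{path}:{lineno}: bad point_role {rec['point_role']!r}")
            rows.append(rec)
    return pd.DataFrame(rows, columns=ATTACHMENT_COLUMNS)


def write_attachment_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    missing = [c for c in ATTACHMENT_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"attachment table missing columns {missing}")
    out = out[ATTACHMENT_COLUMNS]
    out.to_csv(path, index=False, float_format="%.6g")


def read_curve_csv(path) -> list[MomentArmCurve]:
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: curve table missing columns {missing}")
    curves = []
    for (finger, muscle, joint, dof, source), grp in df.groupby(
        ["finger", "muscle", "joint", "dof", "source"], sort=False
    ):
        grp = grp.sort_values("angle_deg")
        curves.append(
            MomentArmCurve(
                joint,
                dof,
                grp["angle_deg"].to_numpy(),
                grp["moment_arm_mm"].to_numpy(),
                source=source,
                muscle=muscle,
                finger=int(finger),
            )
        )
    return curves


def write_curve_csv(curves, path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "finger": c.finger,
                    "muscle": c.muscle,
                    "joint": c.joint,
                    "dof": c.dof,
                    "angle_deg": c.angles,
                    "moment_arm_mm": c.values,
                    "source": c.source,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# building muscle paths and optimization problems from tables


def muscle_path_from_table(
    table: pd.DataFrame, finger: int, muscle: str, source: str = "optimized"
) -> MusclePath:
    """Assemble the ordered crossing pairs of one muscle from an attachment table."""
    sel = table[
        (table.finger == finger) & (table.muscle == muscle) & (table.source == source)
    ]
    if sel.empty:
        raise KeyError(f"no {source} rows for finger {finger} muscle {muscle}")
    pairs = []
    for joint in sorted(sel.joint.unique(), key=_JOINT_ORDER.__getitem__):
        rows = sel[sel.joint == joint].set_index("point_role")
        pairs.append(
            CrossingPair(
                joint,
                AttachmentPoint(
                    rows.loc["proximal", "segment"],
                    (
                        float(rows.loc["proximal", "x_mm"]),
                        float(rows.loc["proximal", "y_mm"]),
                        float(rows.loc["proximal", "z_mm"]),
                    ),
                ),
                AttachmentPoint(
                    rows.loc["distal", "segment"],
                    (
                        float(rows.loc["distal", "x_mm"]),
                        float(rows.loc["distal", "y_mm"]),
                        float(rows.loc["distal", "z_mm"]),
                    ),
                ),
            )
        )
    return MusclePath(muscle, finger, tuple(pairs))


def all_muscle_paths(table: pd.DataFrame, source: str = "optimized") -> list[MusclePath]:
    """All (finger, muscle) paths in a table: 4 fingers x 10 muscles for fixtures."""
    paths = []
    for finger in sorted(table.finger.unique()):
        sub = table[table.finger == finger]
        for muscle in sub.muscle.unique():
            paths.append(muscle_path_from_table(table, int(finger), muscle, source))
    return paths


def pair_vector(path: MusclePath, joint: str) -> np.ndarray:
    """(proximal xyz, distal xyz) of the pair straddling ``joint``."""
    pair = path.pair_for(joint)
    return np.concatenate([pair.proximal.xyz(), pair.distal.xyz()])


def bounds_for_pair(
    chain: FingerChain, scale: ScaleSet, path: MusclePath, joint: str
) -> tuple[np.ndarray, np.ndarray]:
    """Skin-surface box bounds for the free pair, per attachment segment."""
    pair = path.pair_for(joint)
    bp = skin_bounds(chain, scale, pair.proximal.segment, joint)
    bd = skin_bounds(chain, scale, pair.distal.segment, joint)
    lb = np.concatenate([bp.lb, bd.lb])
    ub = np.concatenate([bp.ub, bd.ub])
    return lb, ub


def make_problem(
    chain: FingerChain,
    path: MusclePath,
    joint: str,
    targets,
    scale: ScaleSet | None = None,
    measured_x: np.ndarray | None = None,
    seed: int = 0,
    n_starts: int = 26,
    m: int = 100,
    sa: SASchedule | None = None,
    hj: HJSettings | None = None,
    wraps: dict[str, WrapCylinder] | None = None,
) -> OptProblem:
    """Glue fixtures, bounds and targets into a ready-to-solve problem.

    ``measured_x`` defaults to the template pair itself (the usual starting
    estimate); it seeds the start list and anchors candidate selection.
    """
    scale = scale or index_scale_set()
    lb, ub = bounds_for_pair(chain, scale, path, joint)
    if measured_x is None:
        measured_x = pair_vector(path, joint)
    measured_x = np.clip(np.asarray(measured_x, dtype=float), lb, ub)
    starts = make_start_points((lb, ub), measured_x, n_starts, seed)
    kwargs = {}
    if sa is not None:
        kwargs["sa"] = sa
    if hj is not None:
        kwargs["hj"] = hj
    return OptProblem(
        chain,
        path,
        joint,
        tuple(targets),
        lb,
        ub,
        epsilon=epsilon_for(path.muscle),
        m=m,
        seed=seed,
        measured_x=measured_x,
        x0_list=tuple(starts),
        wraps=wraps,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# synthetic targets


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth attachments plus a noise model for recovery experiments."""

    true_path: MusclePath
    noise_sd: float = 0.0  # mm, i.i.d. Gaussian per grid point
    m: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_synthetic_targets(
    spec: SyntheticSpec,
    chain: FingerChain,
    wraps: dict[str, WrapCylinder] | None = None,
) -> list[MomentArmCurve]:
    """Model moment-arm curves from the true attachments, plus seeded noise.

    One flexion curve per crossed joint; at MCP also the ab/adduction moment
    arm sampled over the flexion sweep (straight-chord model) -- the quantity
    the optimizer's inequality constraint bounds.  ``source`` is set to
    ``measured`` because these stand in for experimentally derived targets.
    """
    if wraps is None:
        wraps = default_wrap_set(chain, spec.true_path.muscle)
    rng = np.random.default_rng(spec.seed)
    curves = []
    for pair in spec.true_path.pairs:
        for dof in chain.joint(pair.joint).dof_names:
            use_wraps = wraps if dof == "flexion" else None
            angles, postures = posture_grid(chain, pair.joint, "flexion", spec.m)
            values = np.array(
                [
                    moment_arm(chain, qi, spec.true_path, pair.joint, dof, wraps=use_wraps)
                    for qi in postures
                ]
            )
            if spec.noise_sd > 0:
                values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
            curves.append(
                MomentArmCurve(
                    pair.joint,
                    dof,
                    angles,
                    values,
                    source="measured",
                    muscle=spec.true_path.muscle,
                    finger=spec.true_path.finger,
                )
            )
    return curves
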