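"""Validation metrics: VAF, RMS error, attachment distances and reports.

VAF (variance accounted for) between a target curve r and a model curve r-hat:

    VAF = 100 * [1 - sum((r - r_hat)^2) / sum(r^2)]

VAF is 100 exactly when the residual vanishes, can be negative for poor
fits, and is undefined for an identically-zero target.  RMS error is the
root mean squared residual in mm.  Attachment placement error is reported
as the Euclidean distance (Delta-R) between model and measured sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "vaf",
    "rms_error",
    "euclidean_delta",
    "percent_error",
    "ComparisonReport",
    "attachment_report",
]


def _pair(r, r_hat):
    r = np.asarray(r, dtype=float)
    r_hat = np.asarray(r_hat, dtype=float)
    if r.shape != r_hat.shape:
        raise ValueError(f"length mismatch: {r.shape} vs {r_hat.shape}")
    return r, r_hat


def vaf(r, r_hat) -> float:
    """Variance accounted for, percent (not clamped; may be negative)."""
    r, r_hat = _pair(r, r_hat)
    denom = float(np.sum(r * r))
    if denom <= 0.0:
        raise ValueError("VAF undefined for a zero target curve")
    return 100.0 * (1.0 - float(np.sum((r - r_hat) ** 2)) / denom)


def rms_error(r, r_hat) -> float:
    """Root mean squared residual (mm)."""
    r, r_hat = _pair(r, r_hat)
    return float(np.sqrt(np.mean((r - r_hat) ** 2)))


def percent_error(r, r_hat) -> float:
    """100 * RMS / |mean target|; a display convention, not a fit criterion."""
    r, r_hat = _pair(r, r_hat)
    mean = abs(float(np.mean(r)))
    if mean == 0.0:
        raise ValueError("percent error undefined for a zero-mean target")
    return 100.0 * rms_error(r, r_hat) / mean


def euclidean_delta(a, b) -> float:
    """Euclidean distance (mm) between two attachment points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


_KEY = ["finger", "joint", "muscle", "point_role"]


@dataclass(frozen=True)
class ComparisonReport:
    """Per-attachment Delta-R table plus summary statistics."""

    per_point: pd.DataFrame  # key columns + delta_r_mm (+ printed value if any)
    mean_delta_r: float
    n_points: int

    def per_finger(self) -> dict[int, float]:
        return self.per_point.groupby("finger")["delta_r_mm"].mean().to_dict()

    def summary(self) -> dict:
        return {
            "mean_delta_r_mm": self.mean_delta_r,
            "n_points": self.n_points,
            "per_finger": {int(k): float(v) for k, v in self.per_finger().items()},
        }


def attachment_report(optimized: pd.DataFrame, measured: pd.DataFrame) -> ComparisonReport:
    """Per-point Euclidean distances between two attachment tables.

    Both tables need the key columns finger/joint/muscle/point_role and
    coordinates x_mm/y_mm/z_mm; the key sets must match exactly.
    """
    o = optimized.set_index(_KEY).sort_index()
    m = measured.set_index(_KEY).sort_index()
    missing = set(o.index).symmetric_difference(m.index)
    if missing:
        raise KeyError(f"attachment tables do not share keys; mismatched: {sorted(missing)[:10]}")
    coords = ["x_mm", "y_mm", "z_mm"]
    delta = np.sqrt(((o[coords] - m[coords]) ** 2).sum(axis=1))
    per_point = o.reset_index()[_KEY].copy()
    per_point["delta_r_mm"] = delta.to_numpy()
    if "delta_r_mm" in optimized.columns:
        per_point["printed_delta_r_mm"] = o["delta_r_mm"].to_numpy()
    return ComparisonReport(per_point, float(delta.mean()), int(len(delta)))
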