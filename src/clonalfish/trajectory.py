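"""Trajectory-derived behavior metrics.

Two daily measures are computed from xy position time series sampled at a
nominal 0.2 s interval: *activity*, the average distance moved per second
(total path length over valid elapsed time) during the activity phase, and
*feeding time*, the minutes spent inside a fixed rectangular feeding zone
(5 x 13 cm around the stationary food patch) during the feeding phase.

Conventions (fixed, documented):

- Gaps: consecutive sample pairs whose elapsed time exceeds
  ``max_gap_factor * step_s`` (default 3x) are excluded from both path length
  and elapsed time; nothing is interpolated.
- Zone membership is boundary-inclusive.
- Each feeding-phase sample carries ``step_s`` seconds of dwell
  (left-closed attribution).
- Centimeters and seconds internally; minutes only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregationError, FormatError, InsufficientDataError, ValidationError

#: canonical column names of the trajectory CSV dialect
TRAJECTORY_COLUMNS = ["individual_id", "day", "phase", "t_s", "x_cm", "y_cm"]


@dataclass(frozen=True)
class ZoneSpec:
    """Axis-aligned feeding-zone rectangle (cm)."""

    x_min: float
    y_min: float
    width_cm: float = 5.0
    height_cm: float = 13.0

    def __post_init__(self):
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValidationError("zone width_cm and height_cm must be > 0")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test."""
        return (
            (x >= self.x_min)
            & (x <= self.x_min + self.width_cm)
            & (y >= self.y_min)
            & (y <= self.y_min + self.height_cm)
        )


def _validated_txy(traj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = traj["t_s"].to_numpy(dtype=float)
    x = traj["x_cm"].to_numpy(dtype=float)
    y = traj["y_cm"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(t).all()):
        raise FormatError("non-finite coordinates or timestamps")
    if np.any(np.diff(t) <= 0):
        raise FormatError("timestamps must be strictly increasing")
    return t, x, y


def compute_activity(
    traj: pd.DataFrame, step_s: float = 0.2, max_gap_factor: float = 3.0
) -> float:
    """Average distance moved (cm) per second over the track.

    Total Euclidean path length over valid consecutive sample pairs divided
    by the total valid elapsed time.  Pairs separated by more than
    ``max_gap_factor * step_s`` are treated as recording gaps and excluded.
    """
    if len(traj) < 2:
        raise InsufficientDataError("activity needs >= 2 samples")
    t, x, y = _validated_txy(traj)
    dt = np.diff(t)
    valid = dt <= max_gap_factor * step_s
    if not valid.any():
        raise InsufficientDataError("no valid consecutive sample pairs")
    dist = np.hypot(np.diff(x), np.diff(y))[valid]
    elapsed = dt[valid].sum()
    return float(dist.sum() / elapsed)


def compute_feeding_time(
    traj: pd.DataFrame, zone: ZoneSpec, step_s: float = 0.2
) -> float:
    """Minutes spent inside the feeding zone (step_s of dwell per sample)."""
    if len(traj) < 1:
        raise InsufficientDataError("feeding time needs >= 1 sample")
    t, x, y = _validated_txy(traj)
    inside = zone.contains(x, y)
    return float(inside.sum() * step_s / 60.0)


def recording_duration_min(traj: pd.DataFrame, step_s: float = 0.2) -> float:
    """Observed recording duration in minutes (one step per sample)."""
    return len(traj) * step_s / 60.0


def summarize_day(
    trajs: pd.DataFrame, zone: ZoneSpec, step_s: float = 0.2
) -> dict:
    """One DailyBehavior record for a single individual-day.

    Absent phases yield missing (NaN) metrics; they are propagated, never
    imputed.  Duplicate timestamps within a phase raise.
    """
    ids = trajs["individual_id"].unique()
    days = trajs["day"].unique()
    if len(ids) != 1 or len(days) != 1:
        raise AggregationError(
            f"summarize_day got {len(ids)} individuals x {len(days)} days"
        )
    phases = set(trajs["phase"].unique())
    unknown = phases - {"activity", "feeding"}
    if unknown:
        raise FormatError(f"unknown phase labels: {sorted(unknown)}")
    if not phases:
        raise InsufficientDataError("no phase data for individual-day")
    rec = {
        "individual_id": ids[0],
        "day": int(days[0]),
        "activity_cm_per_s": np.nan,
        "feeding_min": np.nan,
        "activity_duration_min": np.nan,
        "feeding_duration_min": np.nan,
    }
    if "activity" in phases:
        sub = trajs[trajs["phase"] == "activity"].sort_values("t_s")
        rec["activity_cm_per_s"] = compute_activity(sub, step_s=step_s)
        rec["activity_duration_min"] = recording_duration_min(sub, step_s)
    if "feeding" in phases:
        sub = trajs[trajs["phase"] == "feeding"].sort_values("t_s")
        rec["feeding_min"] = compute_feeding_time(sub, zone, step_s=step_s)
        rec["feeding_duration_min"] = recording_duration_min(sub, step_s)
    return rec


def summarize_trajectories(
    trajectories: pd.DataFrame, zone: ZoneSpec, step_s: float = 0.2
) -> pd.DataFrame:
    """DailyBehavior table for a full trajectory table (one row per
    individual-day)."""
    missing = [c for c in TRAJECTORY_COLUMNS if c not in trajectories.columns]
    if missing:
        raise FormatError(f"trajectory table missing columns: {missing}")
    rows = [
        summarize_day(sub, zone, step_s=step_s)
        for _, sub in trajectories.groupby(["individual_id", "day"], sort=True)
    ]
    return pd.DataFrame(rows)


def validate_behavior_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Check a DailyBehavior table for duplicate individual-day records."""
    dup = behavior.duplicated(subset=["individual_id", "day"])
    if dup.any():
        bad = behavior.loc[dup, ["individual_id", "day"]].to_records(index=False)
        raise AggregationError(f"duplicate individual-day records: {list(bad)[:5]}")
    return behavior
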