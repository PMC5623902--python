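"""Ancillary preclinical scalar formulas: tumor volume, T/C%, 2^-ddCt.

These are the standard xenograft and qPCR readout formulas: caliper
tumor volume ``length x width^2 x 0.5`` (mm^3), the treated-over-control
percentage of tumor-volume change, and relative expression fold change
from cycle thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("combosurf")

__all__ = [
    "TumorMeasurement",
    "GroupTrajectory",
    "tumor_volume",
    "t_over_c",
    "fold_change_ddct",
    "trajectories_from_measurements",
]


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper reading: the longer axis is ``length``."""

    length: float  # mm
    width: float  # mm
    day: int = 0

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise ValueError("length and width must be positive")
        if not (math.isfinite(self.length) and math.isfinite(self.width)):
            raise ValueError("length and width must be finite")
        if self.width > self.length:
            raise ValueError(
                f"width ({self.width}) exceeds length ({self.length}); axes swapped?"
            )


@dataclass(frozen=True)
class GroupTrajectory:
    """Per-animal tumor-volume series for one treatment group.

    ``volumes`` is a DataFrame with columns ``animal_id``, ``day``,
    ``volume_mm3``.
    """

    group: str
    volumes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal_id", "day", "volume_mm3"}
        missing = required - set(self.volumes.columns)
        if missing:
            raise ValueError(f"trajectory missing columns: {sorted(missing)}")

    def volumes_at(self, day: int) -> pd.Series:
        sub = self.volumes[self.volumes["day"] == day]
        return sub.set_index("animal_id")["volume_mm3"]


def tumor_volume(m: TumorMeasurement) -> float:
    """Caliper tumor volume in mm^3: (length x width^2) x 0.5."""
    return m.length * m.width**2 * 0.5


def t_over_c(
    treated: GroupTrajectory,
    control: GroupTrajectory,
    start_day: int,
    end_day: int,
) -> float:
    """Treated-over-control percentage of tumor-volume change.

    ``100 x mean(treated per-animal change) / mean(control per-animal
    change)`` between ``start_day`` and ``end_day``.  Animals without a
    measurement at both days are excluded (logged).  Negative values
    indicate tumor regression; a non-positive control change leaves T/C
    undefined and returns NaN with a warning.
    """
    changes = []
    for traj in (treated, control):
        v0 = traj.volumes_at(start_day)
        v1 = traj.volumes_at(end_day)
        if v0.empty or v1.empty:
            raise ValueError(
                f"group {traj.group!r} lacks measurements at day "
                f"{start_day} or {end_day}"
            )
        common = v0.index.intersection(v1.index)
        dropped = len(v0.index.union(v1.index)) - len(common)
        if dropped:
            logger.info(
                "group %r: excluded %d animal(s) missing a measurement",
                traj.group,
                dropped,
            )
        changes.append(float((v1[common] - v0[common]).mean()))
    treated_change, control_change = changes
    if control_change <= 0:
        logger.warning(
            "control volume change %.3g <= 0: T/C%% undefined", control_change
        )
        return math.nan
    return 100.0 * treated_change / control_change


def fold_change_ddct(delta_delta_ct: float) -> float:
    """Relative expression fold change: 2^(-ddCt).

    Sign convention: dCt = Ct_target - Ct_reference and
    ddCt = dCt_treated - dCt_control, so a one-cycle increase halves the
    reported expression.
    """
    if not math.isfinite(delta_delta_ct):
        raise ValueError("delta_delta_ct must be finite")
    return 2.0 ** (-delta_delta_ct)


def trajectories_from_measurements(df: pd.DataFrame) -> dict[str, GroupTrajectory]:
    """Build per-group trajectories from a caliper measurement table.

    Expects columns ``animal_id, group, day, length_mm, width_mm``; volumes
    are computed with :func:`tumor_volume`.
    """
    required = {"animal_id", "group", "day", "length_mm", "width_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    vols = [
        tumor_volume(TumorMeasurement(r.length_mm, r.width_mm, int(r.day)))
        for r in df.itertuples()
    ]
    out = df[["animal_id", "group", "day"]].copy()
    out["volume_mm3"] = vols
    return {
        g: GroupTrajectory(group=str(g), volumes=sub.drop(columns="group").reset_index(drop=True))
        for g, sub in out.groupby("group")
    }
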