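"""Trajectory tables: per-participant, per-timestep poses plus I/O.

The on-disk format is a plain UTF-8 CSV with header
``trial_id,participant_id,t,x,y,heading,informed``, one frame per row,
'.' decimal separator.  In memory a :class:`TrajectoryTable` wraps a pandas
DataFrame with those columns together with the :class:`~.config.TrialConfig`
it was recorded under.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .config import TrialConfig

COLUMNS = ["trial_id", "participant_id", "t", "x", "y", "heading", "informed"]


class TrajectoryError(ValueError):
    """Raised for malformed trajectory tables."""


@dataclass
class TrajectoryTable:
    """Validated per-frame poses for all participants of one trial."""

    frames: pd.DataFrame
    config: TrialConfig

    def __post_init__(self) -> None:
        self.frames = self.frames.reset_index(drop=True)
        validate_frames(self.frames, self.config)

    @property
    def trial_id(self) -> str:
        return str(self.frames["trial_id"].iloc[0])

    def participant_ids(self) -> list[str]:
        return sorted(self.frames["participant_id"].unique())

    def times(self) -> np.ndarray:
        return np.sort(self.frames["t"].unique())

    def duration(self) -> float:
        return float(self.frames["t"].max())

    def participant(self, pid: str) -> pd.DataFrame:
        sub = self.frames[self.frames["participant_id"] == pid]
        if sub.empty:
            raise KeyError(f"unknown participant {pid!r}")
        return sub.sort_values("t").reset_index(drop=True)

    def positions_at(self, t: float) -> pd.DataFrame:
        """All participants' rows at timestamp ``t`` (indexed by participant)."""
        sub = self.frames[np.isclose(self.frames["t"], t)]
        if sub.empty:
            raise KeyError(f"no frames at t={t}")
        return sub.set_index("participant_id").sort_index()


def validate_frames(df: pd.DataFrame, config: TrialConfig) -> None:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"missing columns: {missing}")
    if df.empty:
        raise TrajectoryError("empty trajectory table")
    if (df["t"] < 0).any():
        bad = df.loc[df["t"] < 0].iloc[0]
        raise TrajectoryError(f"negative timestamp t={bad['t']} "
                              f"(participant {bad['participant_id']})")
    ext = config.arena_half_extent
    out = df[(df["x"].abs() > ext) | (df["y"].abs() > ext)]
    if not out.empty:
        bad = out.iloc[0]
        raise TrajectoryError(
            f"position ({bad['x']}, {bad['y']}) outside arena bound +/-{ext} m "
            f"(participant {bad['participant_id']}, t={bad['t']})"
        )
    dup = df.duplicated(subset=["participant_id", "t"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise TrajectoryError(
            f"duplicated frame for (participant {bad['participant_id']}, "
            f"t={bad['t']})"
        )
    pids = sorted(df["participant_id"].unique())
    expected = config.participant_ids()
    if pids != expected:
        raise TrajectoryError(
            f"participants {pids} do not match config ({expected})"
        )
    grids = {pid: tuple(np.sort(df.loc[df["participant_id"] == pid, "t"]))
             for pid in pids}
    if len(set(grids.values())) != 1:
        raise TrajectoryError("participants do not share identical timestamps")


def write_trajectories(table: TrajectoryTable, path: str | Path) -> None:
    """Write the trajectory CSV dialect (round-trips bit-identically)."""
    df = table.frames.copy()
    df["informed"] = df["informed"].astype(int)
    df.to_csv(path, index=False, columns=COLUMNS, float_format="%.6f")


def load_trajectories(path: str | Path, config: TrialConfig) -> TrajectoryTable:
    """Load and validate a trajectory CSV against a trial configuration."""
    df = pd.read_csv(path, dtype={"trial_id": str, "participant_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing columns: {missing}")
    df["informed"] = df["informed"].astype(bool)
    for pid, sub in df.groupby("participant_id"):
        dt = np.diff(sub["t"].to_numpy())
        if (dt <= 0).any():
            i = int(np.argmax(dt <= 0))
            raise TrajectoryError(
                f"{path}: non-monotone timestamps for participant {pid} "
                f"around t={sub['t'].iloc[i + 1]}"
            )
    return TrajectoryTable(df, config)


def velocity(table: TrajectoryTable, participant: str, t: float) -> np.ndarray:
    """Finite-difference velocity (m/s) of one participant at timestamp ``t``.

    Central difference at interior timestamps, one-sided at the ends.
    """
    sub = table.participant(participant)
    ts = sub["t"].to_numpy()
    if len(ts) < 2:
        raise TrajectoryError("cannot differentiate a single-frame series")
    idx = np.flatnonzero(np.isclose(ts, t))
    if idx.size == 0:
        raise TrajectoryError(f"t={t} is not a timestamp of {participant}")
    i = int(idx[0])
    xy = sub[["x", "y"]].to_numpy()
    lo, hi = max(i - 1, 0), min(i + 1, len(ts) - 1)
    return (xy[hi] - xy[lo]) / (ts[hi] - ts[lo])


def velocities_at(table: TrajectoryTable, t: float) -> dict[str, np.ndarray]:
    """Velocity of every participant at timestamp ``t``."""
    return {pid: velocity(table, pid, t) for pid in table.participant_ids()}


def resample_1hz(table: TrajectoryTable) -> TrajectoryTable:
    """Keep the bin-start sample of each one-second bin (idempotent).

    Returns one frame per participant per integer second present in the
    table, i.e. the frame at ``t = 0, 1, 2, ...``.
    """
    df = table.frames
    keep = np.isclose(df["t"] % 1.0, 0.0) | np.isclose(df["t"] % 1.0, 1.0)
    out = df.loc[keep].copy()
    out["t"] = np.round(out["t"]).astype(float)
    if out.empty:
        raise TrajectoryError("no integer-second frames to resample")
    return TrajectoryTable(out.reset_index(drop=True), table.config)
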