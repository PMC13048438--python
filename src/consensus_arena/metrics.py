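"""Social and spatial metrics.

* ``delta_social`` — disagreeing social information: the largest supporter
  count among the options the focal individual has *not* selected minus the
  supporter count of its current selection, counting the other group
  members only.
* ``interplayer_distance`` — mean pairwise distance among the avatars.
* ``mean_distance_to_site`` — mean distance of the avatars to a given site's
  centre (used with the eventually chosen site).
* ``com_distance`` / ``approach_speed`` — distance to the group's centre of
  mass (all avatars, focal included) and the focal's active approach speed
  toward it: speed times the negative time derivative of the distance to
  the COM (positive while actively approaching; units m^2/s^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .config import SITE_LABELS, Site
from .trajectory import TrajectoryTable, velocity


@dataclass(frozen=True)
class SupportCounts:
    """Per-site supporter counts over the *other* individuals."""

    counts: Mapping[str, int]
    focal_site: str | None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")


def delta_social(counts: SupportCounts) -> int:
    """Largest supporter count among unselected options minus own support."""
    if counts.focal_site is None:
        raise ValueError("focal has no current opinion; DeltaSocial undefined")
    own = counts.counts.get(counts.focal_site, 0)
    alts = [v for k, v in counts.counts.items() if k != counts.focal_site]
    for lab in SITE_LABELS:
        if lab != counts.focal_site and lab not in counts.counts:
            alts.append(0)
    return int(max(alts) - own)


def interplayer_distance(positions: np.ndarray) -> float:
    """Mean pairwise Euclidean distance of N >= 2 positions."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise ValueError("need at least two positions")
    return float(pdist(positions).mean())


def mean_distance_to_site(positions: np.ndarray, site: Site) -> float:
    """Mean distance of the participants to a site's centre."""
    positions = np.asarray(positions, dtype=float)
    return float(np.linalg.norm(positions - np.asarray(site.center), axis=1).mean())


def _positions_matrix(table: TrajectoryTable) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(participant ids, shared timestamps, positions (P, T, 2))."""
    pids = table.participant_ids()
    ts = table.times()
    pos = np.empty((len(pids), len(ts), 2))
    for i, pid in enumerate(pids):
        sub = table.participant(pid)
        pos[i] = sub[["x", "y"]].to_numpy()
    return pids, ts, pos


def com_distance(table: TrajectoryTable, participant: str, t: float) -> float:
    """Distance from a participant to the group centre of mass at time t."""
    frame = table.positions_at(t)
    pos = frame[["x", "y"]].to_numpy()
    com = pos.mean(axis=0)
    me = frame.loc[participant, ["x", "y"]].to_numpy(dtype=float)
    return float(np.linalg.norm(me - com))


def approach_speed(table: TrajectoryTable, participant: str, t: float,
                   window: float = 1.0) -> float:
    """Active approach speed toward the COM (m^2/s^2) at time ``t``.

    The derivative of the focal's distance to the COM is estimated by a
    symmetric finite difference across ``window`` seconds (clipped to the
    series ends); it is negated and multiplied by the focal's speed so that
    approaching actively yields positive values.
    """
    ts = table.times()
    if not np.isclose(ts, t).any():
        raise ValueError(f"t={t} outside the table's grid")
    h = window / 2.0
    lo = ts[ts <= t - h + 1e-9].max(initial=np.nan)
    hi = ts[ts >= t + h - 1e-9].min(initial=np.nan)
    if np.isnan(lo):
        lo = ts.min()
    if np.isnan(hi):
        hi = ts.max()
    if np.isclose(hi, lo):
        raise ValueError("window does not fit inside the series")
    d_lo = com_distance(table, participant, lo)
    d_hi = com_distance(table, participant, hi)
    deriv = (d_hi - d_lo) / (hi - lo)
    v = np.linalg.norm(velocity(table, participant, t))
    return float(v * (-deriv))


def support_counts(series_frame: pd.DataFrame, focal: str) -> SupportCounts:
    """Support counts at one timestamp from an opinion-series slice.

    ``series_frame`` holds one row per participant (columns
    ``participant_id, site``); supporters are others with a non-null site.
    """
    others = series_frame[series_frame["participant_id"] != focal]
    counts = {lab: int((others["site"] == lab).sum()) for lab in SITE_LABELS}
    focal_site = series_frame.loc[
        series_frame["participant_id"] == focal, "site"]
    fs = focal_site.iloc[0] if len(focal_site) else None
    return SupportCounts(counts, None if pd.isna(fs) else fs)


def metrics_table(table: TrajectoryTable, series: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-second covariates for the event and model stages.

    Expects a 1 Hz trajectory table and the matching opinion series.
    Columns: ``trial_id, participant_id, t, delta_social, dist_to_site,
    on_correct, com_dist, approach_speed, interplayer_dist, informed``.
    DeltaSocial and the distance to the supported site are NaN for seconds
    without an opinion.
    """
    cfg = table.config
    pids, ts, pos = _positions_matrix(table)
    P, T = len(pids), len(ts)
    centers = np.array([s.center for s in cfg.sites])

    # opinion codes (P, T)
    smap = {lab: i for i, lab in enumerate(SITE_LABELS)}
    codes = np.full((P, T), -1, dtype=np.int64)
    pidx = {pid: i for i, pid in enumerate(pids)}
    tidx = {int(t): j for j, t in enumerate(np.round(ts).astype(int))}
    for pid, t, site in series[["participant_id", "t", "site"]].itertuples(index=False):
        if site is not None and not pd.isna(site):
            codes[pidx[pid], tidx[int(t)]] = smap[site]

    onehot = np.zeros((P, T, 4))
    has = codes >= 0
    onehot[np.nonzero(has)[0], np.nonzero(has)[1], codes[has]] = 1.0
    totals = onehot.sum(axis=0, keepdims=True)
    others = totals - onehot                                   # (P, T, 4)
    own = np.clip(codes, 0, 3)
    own_cnt = np.take_along_axis(others, own[..., None], -1)[..., 0]
    alts = others.copy()
    np.put_along_axis(alts, own[..., None], -np.inf, -1)
    ds = np.where(has, alts.max(axis=-1) - own_cnt, np.nan)

    dist_to_site = np.where(
        has, np.linalg.norm(pos - centers[own], axis=-1), np.nan)
    correct = smap[cfg.correct_site]
    on_correct = np.where(has, (codes == correct).astype(float), np.nan)

    com = pos.mean(axis=0)                                     # (T, 2)
    com_d = np.linalg.norm(pos - com[None], axis=-1)           # (P, T)
    # symmetric differences on the 1 Hz grid (one-sided at the ends)
    lo = np.maximum(np.arange(T) - 1, 0)
    hi = np.minimum(np.arange(T) + 1, T - 1)
    span = (ts[hi] - ts[lo])[None, :]
    vel = (pos[:, hi] - pos[:, lo]) / span[..., None]
    speed = np.linalg.norm(vel, axis=-1)
    dcom_dt = (com_d[:, hi] - com_d[:, lo]) / span
    appr = speed * (-dcom_dt)

    ipd = np.array([pdist(pos[:, j]).mean() for j in range(T)]) if P >= 2 \
        else np.full(T, np.nan)

    informed = np.array([pid in cfg.informed_ids for pid in pids])
    out = pd.DataFrame({
        "trial_id": np.repeat(table.trial_id, P * T),
        "participant_id": np.repeat(pids, T),
        "t": np.tile(np.round(ts).astype(int), P),
        "delta_social": ds.ravel(),
        "dist_to_site": dist_to_site.ravel(),
        "on_correct": on_correct.ravel(),
        "com_dist": com_d.ravel(),
        "approach_speed": appr.ravel(),
        "interplayer_dist": np.tile(ipd, P),
        "informed": np.repeat(informed, T),
    })
    return out
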