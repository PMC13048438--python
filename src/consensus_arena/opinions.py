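"""Movement-based opinion extraction.

An avatar supports a candidate site if it is either *moving toward* it (speed
above a small threshold and the angle between the velocity vector and the
straight line to the site centre below 30 degrees) or *occupying* it
(essentially stationary and positioned inside the site disc).  Applied at
the start of every one-second bin this yields a categorical opinion time
series per participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SITE_LABELS, Site
from .trajectory import TrajectoryTable

ANGLE_MAX_DEG = 30.0
SPEED_EPS = 0.1  # m/s; "not moving" tolerance under finite differencing

MODE_NONE, MODE_MOVING, MODE_OCCUPYING = "none", "moving_toward", "occupying"


@dataclass(frozen=True)
class Opinion:
    site: str | None
    mode: str

    def __post_init__(self) -> None:
        if (self.site is None) != (self.mode == MODE_NONE):
            raise ValueError("site is None iff mode is 'none'")


def _classify_arrays(pos: np.ndarray, vel: np.ndarray, centers: np.ndarray,
                     radii: np.ndarray, angle_max: float,
                     speed_eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised frame classification.

    ``pos``/``vel`` have shape (M, 2).  Returns integer site codes (-1 for
    none) and mode codes (0 none, 1 moving_toward, 2 occupying).
    """
    pos = np.asarray(pos, dtype=float)
    vel = np.asarray(vel, dtype=float)
    M = pos.shape[0]
    speed = np.hypot(vel[:, 0], vel[:, 1])
    to_site = centers[None, :, :] - pos[:, None, :]           # (M, 4, 2)
    dist = np.linalg.norm(to_site, axis=-1)
    dot = (to_site * vel[:, None, :]).sum(-1)
    denom = np.maximum(dist * np.maximum(speed, 1e-300)[:, None], 1e-300)
    cosang = np.clip(dot / denom, -1.0, 1.0)
    ang = np.arccos(cosang)
    amax = math.radians(angle_max)

    site = np.full(M, -1, dtype=np.int64)
    mode = np.zeros(M, dtype=np.int64)

    moving = speed > speed_eps
    # smallest angle wins; exact angle ties broken by the nearer site
    key = np.where(ang < amax, ang + 1e-12 * dist, np.inf)
    best = key.argmin(axis=1)
    ok = moving & np.isfinite(key[np.arange(M), best])
    site[ok] = best[ok]
    mode[ok] = 1

    inside = dist < radii[None, :]
    n_in = inside.sum(axis=1)
    occ = ~moving & (n_in == 1)
    site[occ] = inside[occ].argmax(axis=1)
    mode[occ] = 2
    return site, mode


def classify_frame(position: Sequence[float], velocity_vec: Sequence[float],
                   sites: Sequence[Site], angle_max: float = ANGLE_MAX_DEG,
                   speed_eps: float = SPEED_EPS) -> Opinion:
    """Classify a single frame into an opinion."""
    centers = np.array([s.center for s in sites])
    radii = np.array([s.radius for s in sites])
    s, m = _classify_arrays(np.asarray(position, dtype=float)[None, :],
                            np.asarray(velocity_vec, dtype=float)[None, :],
                            centers, radii, angle_max, speed_eps)
    labels = [st.id for st in sites]
    if m[0] == 0:
        return Opinion(None, MODE_NONE)
    return Opinion(labels[s[0]], MODE_MOVING if m[0] == 1 else MODE_OCCUPYING)


def opinion_series(table: TrajectoryTable, angle_max: float = ANGLE_MAX_DEG,
                   speed_eps: float = SPEED_EPS) -> pd.DataFrame:
    """Per-participant, per-second opinion series.

    Velocities are taken as central finite differences on the table's native
    sampling grid at each bin-start instant; classification happens at 1 Hz.
    Columns: ``trial_id, participant_id, t, site, mode`` (site is ``None``
    when no opinion is held).
    """
    cfg = table.config
    centers = np.array([s.center for s in cfg.sites])
    radii = np.array([s.radius for s in cfg.sites])
    rows = []
    for pid in table.participant_ids():
        sub = table.participant(pid)
        ts = sub["t"].to_numpy()
        xy = sub[["x", "y"]].to_numpy()
        if len(ts) < 2:
            raise ValueError("series too short to differentiate")
        sec_idx = np.flatnonzero(np.isclose(ts % 1.0, 0.0)
                                 | np.isclose(ts % 1.0, 1.0))
        lo = np.maximum(sec_idx - 1, 0)
        hi = np.minimum(sec_idx + 1, len(ts) - 1)
        vel = (xy[hi] - xy[lo]) / (ts[hi] - ts[lo])[:, None]
        site, mode = _classify_arrays(xy[sec_idx], vel, centers, radii,
                                      angle_max, speed_eps)
        rows.append(pd.DataFrame({
            "trial_id": table.trial_id,
            "participant_id": pid,
            "t": np.round(ts[sec_idx]).astype(int),
            "site": [SITE_LABELS[s] if s >= 0 else None for s in site],
            "mode": np.array([MODE_NONE, MODE_MOVING, MODE_OCCUPYING])[mode],
        }))
    if not rows:
        raise ValueError("empty trajectory table")
    return pd.concat(rows, ignore_index=True)
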