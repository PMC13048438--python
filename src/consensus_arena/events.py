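"""Per-second switch/no-switch samples for hazard modelling.

Moving samples: every whole second during which a participant is moving
toward a candidate site, provided a successor bin exists, becomes one
sample.  ``Switch = 1`` when in the next second the participant supports a
*different* site while moving and sustains that new opinion for at least
one further second; everything else (same site, lost opinion, unsustained
1-second excursions) is ``Switch = 0``.

Still samples: analogous for seconds spent occupying a site, with
``TimePassed`` the occupancy duration in seconds; a departure counts as a
switch only when it is a sustained move toward an alternative site.  The
occupancy clock restarts whenever occupation is interrupted for a second
or more.

Covariates (DeltaSocial, distance to the supported site's centre,
OnCorrect) are the bin-start values from
:func:`~consensus_arena.metrics.metrics_table`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import TrialConfig
from .opinions import MODE_MOVING, MODE_NONE, MODE_OCCUPYING

EVENT_COLUMNS = [
    "trial_id", "participant_id", "t", "mode", "switch", "on_correct",
    "delta_social", "distance", "time_passed", "condition", "difficulty",
    "group_id", "group_size", "avatar_type", "informed",
]


def _participant_arrays(sub: pd.DataFrame):
    sub = sub.sort_values("t")
    t = sub["t"].to_numpy(dtype=int)
    if len(t) and not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
        raise ValueError("opinion series bins must be contiguous")
    site = np.array(["" if s is None or pd.isna(s) else s
                     for s in sub["site"]], dtype=object)
    mode = sub["mode"].to_numpy()
    return t, site, mode


def _occupancy_run(site: np.ndarray, mode: np.ndarray) -> np.ndarray:
    """1-based length of the current contiguous same-site occupation."""
    n = len(site)
    occ = mode == MODE_OCCUPYING
    run = np.zeros(n, dtype=int)
    cont = np.zeros(n, dtype=bool)
    cont[1:] = occ[1:] & occ[:-1] & (site[1:] == site[:-1])
    # run[i] = 1 + number of consecutive True cont values ending at i
    c = 0
    for i in range(n):
        if not occ[i]:
            c = 0
        elif cont[i]:
            c += 1
        else:
            c = 0
        run[i] = c + 1 if occ[i] else 0
    return run


def _build(series: pd.DataFrame, metrics: pd.DataFrame, config: TrialConfig,
           still: bool) -> pd.DataFrame:
    want_mode = MODE_OCCUPYING if still else MODE_MOVING
    met = metrics.sort_values(["participant_id", "t"])
    parts = []
    for pid, sub in series.groupby("participant_id", sort=True):
        t, site, mode = _participant_arrays(sub)
        n = len(t)
        if n == 0:
            continue
        msub = met[met["participant_id"] == pid]
        if len(msub) != n or not np.array_equal(
                msub["t"].to_numpy(dtype=int), t):
            msub = (sub[["participant_id", "t"]]
                    .merge(met, on=["participant_id", "t"], how="left"))
        nxt_site = np.append(site[1:], "")
        nxt_mode = np.append(mode[1:], MODE_NONE)
        nxt2_site = np.append(site[2:], ["", ""]) if n >= 2 else np.array([""], dtype=object)
        sustained = ((nxt_mode == MODE_MOVING) & (nxt_site != "")
                     & (nxt_site != site) & (nxt2_site == nxt_site))
        has_succ = np.zeros(n, dtype=bool)
        has_succ[:-1] = True
        keep = (mode == want_mode) & has_succ
        if not keep.any():
            continue
        run = _occupancy_run(site, mode) if still else None
        idx = np.flatnonzero(keep)
        parts.append(pd.DataFrame({
            "trial_id": sub["trial_id"].iloc[0],
            "participant_id": pid,
            "t": t[idx],
            "mode": "still" if still else "moving",
            "switch": sustained[idx].astype(int),
            "on_correct": (site[idx] == config.correct_site).astype(int),
            "delta_social": msub["delta_social"].to_numpy()[idx],
            "distance": (np.full(len(idx), np.nan) if still
                         else msub["dist_to_site"].to_numpy()[idx]),
            "time_passed": (run[idx].astype(float) if still
                            else np.full(len(idx), np.nan)),
            "condition": config.condition,
            "difficulty": config.difficulty,
            "group_id": str(sub["trial_id"].iloc[0]),
            "group_size": config.n_participants,
            "avatar_type": "bulldozer",
            "informed": msub["informed"].to_numpy()[idx],
        }))
    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(parts, ignore_index=True)[EVENT_COLUMNS]


def build_moving_events(series: pd.DataFrame, metrics: pd.DataFrame,
                        config: TrialConfig) -> pd.DataFrame:
    """Switch samples for seconds spent moving toward a candidate site."""
    return _build(series, metrics, config, still=False)


def build_still_events(series: pd.DataFrame, metrics: pd.DataFrame,
                       config: TrialConfig) -> pd.DataFrame:
    """Switch samples for seconds spent occupying a candidate site."""
    return _build(series, metrics, config, still=True)


def merge_events(moving: pd.DataFrame, still: pd.DataFrame) -> pd.DataFrame:
    """Concatenate event tables with a stable ordering and key check."""
    out = pd.concat([moving, still], ignore_index=True)
    keys = out[["trial_id", "participant_id", "t", "mode"]]
    if keys.duplicated().any():
        bad = keys[keys.duplicated()].iloc[0]
        raise ValueError(f"duplicate event key {tuple(bad)}")
    return out.sort_values(["trial_id", "participant_id", "t"],
                           kind="stable").reset_index(drop=True)


def build_events(series: pd.DataFrame, metrics: pd.DataFrame,
                 config: TrialConfig) -> pd.DataFrame:
    """Moving and still samples of one trial, merged."""
    return merge_events(build_moving_events(series, metrics, config),
                        build_still_events(series, metrics, config))
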