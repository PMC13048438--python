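"""Array-based batch analysis of simulated trial chunks.

Computes the same opinion series, covariates and switch events as the
per-trial chain (:func:`consensus_arena.pipeline.trial_events`) but
vectorised over whole chunks of simulated trials, for the large simulation
studies (parameter recovery, calibration sweeps).  The equivalence of the
two paths is asserted by the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SITE_LABELS, TrialConfig
from .opinions import ANGLE_MAX_DEG, SPEED_EPS, _classify_arrays
from .simulate import AgentParams, _BatchEngine, _outcome_record, trial_seed


def _chunk_events(config: TrialConfig, seeds: list[int],
                  trial_ids: list[str], params: AgentParams
                  ) -> tuple[pd.DataFrame, list[dict]]:
    eng = _BatchEngine(config, params, seeds, record=True)
    pos_log, head_log, c_site, c_time, end_tick = eng.run()
    records = [_outcome_record(config, tid, sd, int(c_site[j]), float(c_time[j]))
               for j, (tid, sd) in enumerate(zip(trial_ids, seeds))]

    T, A = eng.T, eng.A
    n_sub = eng.n_sub
    S = int(end_tick.max()) + 1                       # 1 Hz bins, padded
    pos = pos_log[:, :, ::n_sub][:, :, :S].astype(float)      # (T,A,S,2)

    # velocity at bin starts: central on the native grid, one-sided at ends
    dt = 1.0 / n_sub
    f = np.arange(S) * n_sub
    f_lo = np.maximum(f - 1, 0)
    nmax = pos_log.shape[2] - 1
    f_hi = np.minimum(f + 1, nmax)
    span = (f_hi - f_lo) * dt
    vel = (pos_log[:, :, f_hi] - pos_log[:, :, f_lo]).astype(float) \
        / span[None, None, :, None]
    # per-trial final bin: backward difference (frames past the end are dead)
    last = end_tick                                    # (T,)
    fl = last * n_sub
    bwd = (pos_log[np.arange(T), :, fl] - pos_log[np.arange(T), :, fl - 1]
           ).astype(float) / dt
    vel[np.arange(T), :, last] = bwd

    site, mode = _classify_arrays(
        pos.reshape(-1, 2), vel.reshape(-1, 2), eng.centers, eng.radii,
        ANGLE_MAX_DEG, SPEED_EPS)
    site = site.reshape(T, A, S)                       # -1 none
    mode = mode.reshape(T, A, S)                       # 0 none, 1 mov, 2 occ

    valid = np.arange(S)[None, :] <= end_tick[:, None]          # (T,S)
    has = (site >= 0) & valid[:, None, :]

    onehot = np.zeros((T, A, S, 4))
    tt, aa, ss = np.nonzero(has)
    onehot[tt, aa, ss, site[tt, aa, ss]] = 1.0
    totals = onehot.sum(axis=1, keepdims=True)
    others = totals - onehot
    own = np.clip(site, 0, 3)
    own_cnt = np.take_along_axis(others, own[..., None], -1)[..., 0]
    alts = others.copy()
    np.put_along_axis(alts, own[..., None], -np.inf, -1)
    ds = alts.max(axis=-1) - own_cnt
    dist = np.linalg.norm(pos - eng.centers[own], axis=-1)
    on_correct = site == eng.correct

    # occupancy run length (1-based) along the bin axis
    run = np.zeros((T, A, S), dtype=int)
    occ = mode == 2
    run[..., 0] = occ[..., 0].astype(int)
    for s in range(1, S):
        cont = occ[..., s] & occ[..., s - 1] & (site[..., s] == site[..., s - 1])
        run[..., s] = np.where(occ[..., s], np.where(cont, run[..., s - 1] + 1, 1), 0)

    nxt_site = np.concatenate([site[..., 1:], np.full((T, A, 1), -9)], axis=-1)
    nxt_mode = np.concatenate([mode[..., 1:], np.zeros((T, A, 1), int)], axis=-1)
    nxt2_site = np.concatenate([site[..., 2:], np.full((T, A, 2), -9)], axis=-1)
    sustained = ((nxt_mode == 1) & (nxt_site >= 0) & (nxt_site != site)
                 & (nxt2_site == nxt_site))
    has_succ = np.arange(S)[None, None, :] < end_tick[:, None, None]

    informed = np.zeros(A, dtype=bool)
    pids = config.participant_ids()
    for pid in config.informed_ids:
        informed[pids.index(pid)] = True
    tid_arr = np.array(trial_ids, dtype=object)
    pid_arr = np.array(pids, dtype=object)
    site_lab = np.array(SITE_LABELS, dtype=object)

    parts = []
    for still, want in ((False, 1), (True, 2)):
        sel = (mode == want) & has_succ
        tt, aa, ss = np.nonzero(sel)
        if tt.size == 0:
            continue
        parts.append(pd.DataFrame({
            "trial_id": tid_arr[tt],
            "participant_id": pid_arr[aa],
            "t": ss,
            "mode": "still" if still else "moving",
            "switch": sustained[tt, aa, ss].astype(int),
            "on_correct": on_correct[tt, aa, ss].astype(int),
            "delta_social": ds[tt, aa, ss],
            "distance": np.where(still, np.nan, dist[tt, aa, ss]),
            "time_passed": (run[tt, aa, ss].astype(float) if still
                            else np.full(tt.size, np.nan)),
            "condition": config.condition,
            "difficulty": config.difficulty,
            "group_id": tid_arr[tt],
            "group_size": config.n_participants,
            "avatar_type": "bulldozer",
            "informed": informed[aa],
        }))
    if parts:
        events = pd.concat(parts, ignore_index=True)
        events = events.sort_values(["trial_id", "participant_id", "t"],
                                    kind="stable").reset_index(drop=True)
    else:
        events = pd.DataFrame()
    return events, records


def simulate_events(config: TrialConfig, params: AgentParams,
                    n_trials: int, master_seed: int,
                    chunk: int = 250) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_trials`` of one cell and return (events, manifest).

    Per-trial seeds derive from ``master_seed`` exactly as in
    :func:`consensus_arena.simulate.simulate_batch`, so individual trials
    can be re-simulated in isolation.
    """
    seeds = [trial_seed(master_seed, i) for i in range(n_trials)]
    ids = [f"{config.condition}_{config.difficulty}_{i:05d}"
           for i in range(n_trials)]
    ev_parts, records = [], []
    for lo in range(0, n_trials, chunk):
        sl = slice(lo, min(lo + chunk, n_trials))
        ev, recs = _chunk_events(config, seeds[sl], ids[sl], params)
        if len(ev):
            ev_parts.append(ev)
        records.extend(recs)
    events = (pd.concat(ev_parts, ignore_index=True)
              if ev_parts else pd.DataFrame())
    return events, pd.DataFrame(records)
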