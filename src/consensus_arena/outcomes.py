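"""Trial-level outcomes and descriptive summaries.

A trial ends in one of three outcomes: consensus on the correct (largest)
site, consensus on an incorrect site, or no consensus within the time
limit.  A successful group earns ``100 - consensus_time`` gold points.
Summaries report per-cell success proportions with 95% Wilson intervals and
consensus-time statistics over successful trials (plus the correct versus
incorrect comparison).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import SITE_LABELS, TrialConfig
from .trajectory import TrajectoryTable, resample_1hz

OUTCOMES = ("correct_consensus", "incorrect_consensus", "no_consensus")


@dataclass(frozen=True)
class TrialOutcome:
    trial_id: str
    outcome: str
    consensus_site: str | None
    consensus_time: float | None
    success: int
    gold: float
    condition: str
    difficulty: str

    def __post_init__(self) -> None:
        assert (self.success == 1) == (self.outcome == "correct_consensus")
        assert 0.0 <= self.gold <= 100.0
        assert (self.gold > 0) == (self.success == 1) or self.gold == 0


def detect_consensus(table: TrajectoryTable) -> tuple[str | None, float | None]:
    """First whole second at which all avatars sit inside one site disc."""
    table_1hz = resample_1hz(table)
    cfg = table_1hz.config
    pids = table_1hz.participant_ids()
    ts = table_1hz.times()
    pos = np.empty((len(pids), len(ts), 2))
    for i, pid in enumerate(pids):
        pos[i] = table_1hz.participant(pid)[["x", "y"]].to_numpy()
    centers = np.array([s.center for s in cfg.sites])
    radii = np.array([s.radius for s in cfg.sites])
    d = np.linalg.norm(pos[:, :, None, :] - centers[None, None], axis=-1)
    inside = d < radii[None, None, :]
    all_in = inside.all(axis=0)                     # (T, 4)
    hits = np.flatnonzero(all_in.any(axis=1))
    hits = hits[ts[hits] <= cfg.time_limit]
    if hits.size == 0:
        return None, None
    j = int(hits[0])
    return SITE_LABELS[int(all_in[j].argmax())], float(ts[j])


def score_trial(consensus: tuple[str | None, float | None],
                config: TrialConfig, trial_id: str = "trial") -> TrialOutcome:
    """Map a (site, time) consensus result to outcome, success and gold."""
    site, time = consensus
    if site is None:
        outcome, success, gold = "no_consensus", 0, 0.0
    elif site == config.correct_site:
        outcome, success, gold = "correct_consensus", 1, 100.0 - time
    else:
        outcome, success, gold = "incorrect_consensus", 0, 0.0
    return TrialOutcome(trial_id, outcome, site, time, success, gold,
                        config.condition, config.difficulty)


def outcomes_frame(outcomes: Iterable[TrialOutcome]) -> pd.DataFrame:
    return pd.DataFrame([asdict(o) for o in outcomes])


def summarize(outcomes: pd.DataFrame,
              by: Sequence[str] = ("condition", "difficulty")) -> pd.DataFrame:
    """Per-cell success and consensus-time summary.

    Returns one row per cell with the number of trials, the success
    proportion and its 95% Wilson interval, mean +/- SD consensus time over
    successful trials, and the mean time of incorrect-consensus trials.
    Cells with no successful (or no incorrect) trials get NaN time fields.
    """
    rows = []
    for key, sub in outcomes.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(sub)
        k = int(sub["success"].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        t_ok = sub.loc[sub["outcome"] == "correct_consensus", "consensus_time"]
        t_bad = sub.loc[sub["outcome"] == "incorrect_consensus",
                        "consensus_time"]
        rows.append({
            **dict(zip(by, key)),
            "n_trials": n,
            "n_success": k,
            "success_prop": k / n,
            "success_ci_low": lo,
            "success_ci_high": hi,
            "mean_time_correct": t_ok.mean() if len(t_ok) else np.nan,
            "sd_time_correct": t_ok.std(ddof=1) if len(t_ok) > 1 else np.nan,
            "mean_time_incorrect": t_bad.mean() if len(t_bad) else np.nan,
            "n_no_consensus": int((sub["outcome"] == "no_consensus").sum()),
        })
    return pd.DataFrame(rows)


def session_bookkeeping(sessions_by_size: dict[int, int]) -> dict[str, int]:
    """Totals implied by a session-size distribution.

    E.g. ``{7: 9, 8: 11, 9: 8, 10: 4}`` -> 32 sessions, 263 participants.
    """
    n_sessions = sum(sessions_by_size.values())
    n_participants = sum(size * n for size, n in sessions_by_size.items())
    return {"n_sessions": n_sessions, "n_participants": n_participants}
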