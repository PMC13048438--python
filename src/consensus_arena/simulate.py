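"""Agent-based simulator generating arena trajectories.

The generator stands in for human participants: avatars with noisy
perception of site sizes, social copying that strengthens with disagreement,
spatial commitment (switching is less likely close to the chosen site), a
sunk-cost effect (switching is less likely the longer a site has been
occupied), and informed agents that discount social information.

Behaviour model, per 1-second decision tick:

1.  *Perception.*  Each agent perceives each site's radius with additive
    Gaussian noise (one draw per agent, site and trial).  In the local
    condition a site's size is revealed only once the agent has come within
    ``local_visibility_radius`` of its centre; until then it is unknown.
    Informed agents are additionally told the correct site.
2.  *Target selection.*  An agent without a target picks the known site
    maximising ``perceived radius + w_social * supporter count``; in the
    local condition, while no site is known, it travels to an unexplored
    site centre instead (nearest-first by default).
3.  *Switch hazard.*  An agent with a target switches away from it with
    probability ``logistic(alpha + beta_ds*ds + beta_dist*d + beta_time*tau)``
    where ``ds`` is the social disagreement (largest supporter count among
    the alternatives minus the supporters of the current choice, others
    only), ``d`` the distance to the current target's centre and ``tau`` the
    time spent occupying it.  The new target is the most supported
    alternative (ties: larger perceived radius, then label order).  Informed
    agents multiply ``w_social`` and ``beta_ds`` by
    ``informed_social_discount`` and, at discount 0, never abandon the
    correct site.
4.  *Kinematics.*  Avatars rotate toward their goal at up to ``rot_rate``
    rad/s and advance at the fixed ``speed`` whenever the heading error is
    below 15 degrees, halting at a uniformly drawn interior point of the
    target disc.  Integration is Euler at ``sample_rate`` Hz.

A trial ends at the first whole second at which every avatar is inside the
same site disc (consensus), or at the time limit.  All randomness in a trial
comes from a single per-trial seed, so trials are reproducible individually
and in batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SITE_LABELS, TrialConfig
from .trajectory import TrajectoryTable

HEADING_GATE = math.radians(15.0)  # advance only when |heading error| < 15 deg
_ARRIVE_TOL = 1e-6


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of the simulated participants.

    Defaults are the package's standard calibration: perceptual noise of
    1 m SD on site radii, moderate social copying, and hazard coefficients
    chosen so that social disagreement raises, proximity to the chosen site
    lowers, and accumulated occupancy time lowers the per-second switching
    probability.
    """

    sigma_percept: float = 1.0        # radius-perception noise SD, m
    w_social: float = 0.5             # copying weight in target choice, m per supporter
    beta_ds: float = 0.3              # hazard coefficient on social disagreement
    beta_dist: float = 0.03           # hazard coefficient on distance to target, 1/m
    beta_time: float = -0.05          # hazard coefficient on occupancy time, 1/s
    alpha: float = -3.5               # baseline switch log-odds per second
    informed_social_discount: float = 0.0
    explore_policy: str = "nearest_unexplored"
    perception: bool = True           # False: agents ignore site sizes entirely
    initial_choice: str = "greedy"    # "greedy" or "uniform"
    tie_break: str = "deterministic"  # switch-target ties: "deterministic" | "random"
    refractory_s: int = 0             # extra seconds a fresh commitment is held
                                      # before the switch hazard applies again

    def __post_init__(self) -> None:
        if self.sigma_percept < 0:
            raise ValueError("sigma_percept must be >= 0")
        if not 0.0 <= self.informed_social_discount <= 1.0:
            raise ValueError("informed_social_discount must be in [0, 1]")
        if self.w_social < 0:
            raise ValueError("w_social must be >= 0")
        if self.explore_policy not in ("nearest_unexplored", "random_unexplored"):
            raise ValueError(f"unknown explore_policy {self.explore_policy!r}")
        if self.initial_choice not in ("greedy", "uniform"):
            raise ValueError(f"unknown initial_choice {self.initial_choice!r}")
        if self.tie_break not in ("deterministic", "random"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")

    @classmethod
    def noiseless(cls) -> "AgentParams":
        """Zero perception noise, no social influence, switching disabled."""
        return cls(sigma_percept=0.0, w_social=0.0, beta_ds=0.0,
                   beta_dist=0.0, beta_time=0.0, alpha=-np.inf)

    @classmethod
    def random_policy(cls) -> "AgentParams":
        """Chance-level baseline: no perception, uniform initial site choice.

        Agents keep the majority-following switch hazard, so the group still
        converges on a common site; by symmetry that site is the correct one
        in 1/4 of trials.
        """
        return cls(sigma_percept=0.0, w_social=0.0, beta_ds=1.0,
                   beta_dist=0.0, beta_time=0.0, alpha=-2.0,
                   perception=False, initial_choice="uniform",
                   tie_break="random")


@dataclass
class AgentState:
    """Mutable state of one simulated agent (single-agent API)."""

    position: tuple[float, float]
    heading: float
    current_target: str | None = None
    perceived_radii: dict[str, float | None] = field(default_factory=dict)
    occupancy_clock: int = 0
    informed: bool = False
    halt_point: tuple[float, float] | None = None
    explore_waypoint: tuple[float, float] | None = None
    explored: set[str] = field(default_factory=set)
    commit_age: int = 0


def switch_probability(params: AgentParams, ds: float, distance: float,
                       occupancy: float, informed: bool = False) -> float:
    """Per-second probability of abandoning the current target."""
    b_ds = params.beta_ds * (params.informed_social_discount if informed else 1.0)
    eta = (params.alpha + b_ds * ds + params.beta_dist * distance
           + params.beta_time * occupancy)
    return float(expit(eta))


def perceive_sites(state: AgentState, params: AgentParams, config: TrialConfig,
                   rng: np.random.Generator) -> dict[str, float | None]:
    """Draw an agent's per-site radius estimates for one trial.

    In the global and informed-minority conditions every site is perceived
    immediately (true radius plus one Gaussian error per site).  In the
    local condition only sites whose centre lies within
    ``local_visibility_radius`` of the agent are revealed; the rest are
    ``None`` (unknown).  The informed flag itself (knowing the correct
    label) is carried on the state, independent of the noise.
    """
    sigma = params.sigma_percept
    out: dict[str, float | None] = {}
    px, py = state.position
    for s in config.sites:
        noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        if config.condition == "local":
            d = math.hypot(px - s.center[0], py - s.center[1])
            out[s.id] = s.radius + noise if d <= config.local_visibility_radius else None
        else:
            out[s.id] = s.radius + noise
    return out


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _kinematic_substep(pos: np.ndarray, heading: np.ndarray, goal: np.ndarray,
                       dt: float, speed: float, rot_rate: float,
                       move_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step of rotate-then-advance toward ``goal`` (vectorised).

    ``move_mask`` marks agents that are allowed to move at all (active
    trials, not yet halted).  Returns updated (pos, heading).
    """
    delta = goal - pos
    dist = np.hypot(delta[..., 0], delta[..., 1])
    there = dist <= _ARRIVE_TOL
    want = move_mask & ~there
    bearing = np.arctan2(delta[..., 1], delta[..., 0])
    err = _wrap_angle(bearing - heading)
    turn = np.clip(err, -rot_rate * dt, rot_rate * dt)
    heading = np.where(want, _wrap_angle(heading + turn), heading)
    err_new = _wrap_angle(bearing - heading)
    advance = want & (np.abs(err_new) < HEADING_GATE)
    step = np.minimum(speed * dt, dist)
    pos = pos.copy()
    pos[..., 0] = np.where(advance, pos[..., 0] + step * np.cos(heading), pos[..., 0])
    pos[..., 1] = np.where(advance, pos[..., 1] + step * np.sin(heading), pos[..., 1])
    return pos, heading


def _uniform_disc(u: np.ndarray, theta: np.ndarray, center: np.ndarray,
                  radius: np.ndarray) -> np.ndarray:
    """Uniform point in a disc from two pre-drawn uniforms (area-correct)."""
    r = radius * np.sqrt(u)
    return np.stack([center[..., 0] + r * np.cos(2 * np.pi * theta),
                     center[..., 1] + r * np.sin(2 * np.pi * theta)], axis=-1)


class _TrialDraws:
    """All random numbers a trial can consume, pre-drawn from its own seed.

    Pre-drawing makes each trial's outcome a pure function of its seed,
    independent of how trials are batched together.
    """

    def __init__(self, config: TrialConfig, params: AgentParams, seed: int):
        rng = np.random.default_rng(seed)
        A = config.n_participants
        n_ticks = int(round(config.time_limit))
        r = config.start_radius * np.sqrt(rng.uniform(size=A))
        th = rng.uniform(0.0, 2 * np.pi, size=A)
        self.start_pos = np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)
        self.start_heading = rng.uniform(-np.pi, np.pi, size=A)
        self.percept_noise = rng.normal(0.0, 1.0, size=(A, 4)) * params.sigma_percept
        self.hazard_u = rng.uniform(size=(A, n_ticks + 1))
        self.halt_u = rng.uniform(size=(A, n_ticks + 1))
        self.halt_theta = rng.uniform(size=(A, n_ticks + 1))
        self.explore_u = rng.uniform(size=(A, n_ticks + 1))
        self.initial_site = rng.integers(0, 4, size=A)
        self.tie_u = rng.uniform(size=(A, n_ticks + 1, 4))


class _BatchEngine:
    """Vectorised simulation of many same-configuration trials at once."""

    def __init__(self, config: TrialConfig, params: AgentParams,
                 seeds: Sequence[int], record: bool = True,
                 record_truth: bool = False):
        self.config = config
        self.record_truth = record_truth
        self.truth = None
        self.params = params
        self.seeds = list(seeds)
        self.record = record
        self.T = len(self.seeds)
        self.A = config.n_participants
        self.n_ticks = int(round(config.time_limit))
        self.n_sub = int(round(config.sample_rate))
        self.dt = 1.0 / self.n_sub
        self.centers = np.array([s.center for s in config.sites])       # (4,2)
        self.radii = np.array([s.radius for s in config.sites])         # (4,)
        self.correct = SITE_LABELS.index(config.correct_site)
        draws = [_TrialDraws(config, params, s) for s in self.seeds]
        stack = lambda attr: np.stack([getattr(d, attr) for d in draws])
        self.start_pos = stack("start_pos")
        self.start_heading = stack("start_heading")
        self.percept_noise = stack("percept_noise")
        self.hazard_u = stack("hazard_u")
        self.halt_u = stack("halt_u")
        self.halt_theta = stack("halt_theta")
        self.explore_u = stack("explore_u")
        self.initial_site = stack("initial_site")
        self.tie_u = stack("tie_u")

    def run(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
        cfg, par = self.config, self.params
        T, A = self.T, self.A
        pos = self.start_pos.copy()
        heading = self.start_heading.copy()
        target = np.full((T, A), -1, dtype=np.int64)
        halt = pos.copy()
        waypoint = pos.copy()
        has_waypoint = np.zeros((T, A), dtype=bool)
        occupancy = np.zeros((T, A), dtype=np.int64)
        commit_age = np.zeros((T, A), dtype=np.int64)
        explored = np.zeros((T, A, 4), dtype=bool)
        informed = np.zeros(A, dtype=bool)
        for pid in cfg.informed_ids:
            informed[cfg.participant_ids().index(pid)] = True
        informed = np.broadcast_to(informed, (T, A)).copy()

        true_r = self.radii[None, None, :]                              # (1,1,4)
        perceived = true_r + self.percept_noise                         # (T,A,4)
        if cfg.condition == "local":
            known = np.zeros((T, A, 4), dtype=bool)
        else:
            known = np.ones((T, A, 4), dtype=bool)
        if not par.perception:
            perceived = np.zeros_like(perceived)
            known = np.ones((T, A, 4), dtype=bool)

        active = np.ones(T, dtype=bool)
        consensus_site = np.full(T, -1, dtype=np.int64)
        consensus_time = np.full(T, np.nan)
        end_tick = np.full(T, self.n_ticks, dtype=np.int64)

        if self.record:
            n_frames = self.n_ticks * self.n_sub + 1
            pos_log = np.zeros((T, A, n_frames, 2))
            head_log = np.zeros((T, A, n_frames))
            pos_log[:, :, 0] = pos
            head_log[:, :, 0] = heading
        else:
            pos_log = head_log = None
        if self.record_truth:
            truth = {k: np.full((T, A, self.n_ticks), np.nan)
                     for k in ("ds", "dist", "tau", "flip")}

        site_dist = lambda p: np.linalg.norm(
            p[:, :, None, :] - self.centers[None, None, :, :], axis=-1)  # (T,A,4)

        for k in range(self.n_ticks):
            act = active[:, None]                                       # (T,1)

            # 1. local reveal
            if cfg.condition == "local":
                within = site_dist(pos) <= cfg.local_visibility_radius
                known |= within & act[..., None]
            explored |= known

            # 2. support counts over others (focal excluded)
            onehot = np.zeros((T, A, 4))
            sel = target >= 0
            onehot[np.nonzero(sel)[0], np.nonzero(sel)[1], target[sel]] = 1.0
            totals = onehot.sum(axis=1, keepdims=True)                  # (T,1,4)
            counts = totals - onehot                                    # (T,A,4)

            # 3. target selection for agents without one
            need = (target < 0) & act
            if need.any():
                if par.perception:
                    score = np.where(known, perceived + par.w_social * counts,
                                     -np.inf)
                    best = score.argmax(axis=-1)
                    any_known = known.any(axis=-1)
                    commit = need & any_known
                else:
                    best = self.initial_site
                    commit = need.copy()
                if par.initial_choice == "uniform":
                    best = np.broadcast_to(self.initial_site, (T, A))
                best = np.where(informed, self.correct, best)
                new_t = np.where(commit, best, target)
                self._set_halt(halt, new_t, commit, k)
                occupancy[commit] = 0
                commit_age[commit] = 0
                target = new_t
                # exploration waypoints for the rest (local, nothing known)
                explore = need & ~commit
                if explore.any():
                    d_sites = site_dist(pos)
                    d_mask = np.where(explored, np.inf, d_sites)
                    if par.explore_policy == "nearest_unexplored":
                        wp_site = d_mask.argmin(axis=-1)
                    else:
                        unexp = ~explored
                        n_un = np.maximum(unexp.sum(axis=-1), 1)
                        pick = (self.explore_u[:, :, k] * n_un).astype(int)
                        order = np.argsort(~unexp, kind="stable", axis=-1)
                        wp_site = np.take_along_axis(
                            order, pick[..., None], axis=-1)[..., 0]
                    wp = self.centers[wp_site]
                    waypoint = np.where(explore[..., None], wp, waypoint)
                    has_waypoint |= explore
            # 4. switch hazard (only while the choice is being acted on:
            # occupying, halted, or heading within the advance gate --
            # agents mid-rotation do not reconsider)
            goal_now = np.where((target >= 0)[..., None], halt, pos)
            delta_g = goal_now - pos
            dist_g = np.hypot(delta_g[..., 0], delta_g[..., 1])
            bearing_g = np.arctan2(delta_g[..., 1], delta_g[..., 0])
            aligned = (np.abs(_wrap_angle(bearing_g - heading)) < HEADING_GATE) \
                | (dist_g <= _ARRIVE_TOL) | (occupancy > 0)
            hazard_ok = sel & act & aligned & (commit_age >= par.refractory_s)
            if hazard_ok.any():
                own = np.clip(target, 0, 3)
                own_cnt = np.take_along_axis(counts, own[..., None], -1)[..., 0]
                alt = counts.copy()
                np.put_along_axis(alt, own[..., None], -np.inf, -1)
                ds = alt.max(axis=-1) - own_cnt
                d = np.linalg.norm(pos - self.centers[own], axis=-1)
                disc = np.where(informed, par.informed_social_discount, 1.0)
                eta = (par.alpha + par.beta_ds * disc * ds
                       + par.beta_dist * d + par.beta_time * occupancy)
                p = expit(eta)
                locked = (informed & (par.informed_social_discount == 0.0)
                          & (target == self.correct))
                p = np.where(locked, 0.0, p)
                flip = hazard_ok & (self.hazard_u[:, :, k] < p)
                if self.record_truth:
                    m = hazard_ok
                    truth["ds"][:, :, k] = np.where(m, ds, np.nan)
                    truth["dist"][:, :, k] = np.where(m, d, np.nan)
                    truth["tau"][:, :, k] = np.where(m, occupancy, np.nan)
                    truth["flip"][:, :, k] = np.where(m, flip, np.nan)
                if flip.any():
                    if par.tie_break == "random":
                        r_eff = self.tie_u[:, :, k]
                    else:
                        r_eff = np.where(known, perceived, -1e3)
                    alt_score = counts * 1e6 + r_eff
                    np.put_along_axis(alt_score, own[..., None], -np.inf, -1)
                    new_site = alt_score.argmax(axis=-1)
                    target = np.where(flip, new_site, target)
                    self._set_halt(halt, target, flip, k)
                    occupancy[flip] = 0
                    commit_age[flip] = 0

            # 5. kinematics over one second
            goal = np.where((target >= 0)[..., None], halt,
                            np.where(has_waypoint[..., None], waypoint, pos))
            for s in range(self.n_sub):
                pos, heading = _kinematic_substep(
                    pos, heading, goal, self.dt, cfg.speed, cfg.rot_rate,
                    move_mask=np.broadcast_to(act, (T, A)))
                if self.record:
                    f = k * self.n_sub + s + 1
                    pos_log[:, :, f] = pos
                    head_log[:, :, f] = heading

            commit_age = commit_age + 1

            # 6. occupancy clock: inside own target disc and halted
            own = np.clip(target, 0, 3)
            d_own = np.linalg.norm(pos - self.centers[own], axis=-1)
            at_halt = np.linalg.norm(pos - goal, axis=-1) <= _ARRIVE_TOL
            occupying = (target >= 0) & at_halt & (d_own < self.radii[own])
            occupancy = np.where(occupying & act, occupancy + 1, 0)

            # 7. consensus check at time k+1
            dists = site_dist(pos)
            inside = dists < self.radii[None, None, :]
            all_same = inside.all(axis=1)                               # (T,4)
            hit = all_same.any(axis=-1) & active
            if hit.any():
                site_hit = all_same.argmax(axis=-1)
                consensus_site[hit] = site_hit[hit]
                consensus_time[hit] = k + 1
                end_tick[hit] = k + 1
                active &= ~hit
            if not active.any():
                break

        if self.record_truth:
            self.truth = truth
        return pos_log, head_log, consensus_site, consensus_time, end_tick

    def _set_halt(self, halt: np.ndarray, target: np.ndarray,
                  mask: np.ndarray, k: int) -> None:
        tt = np.clip(target, 0, 3)
        pts = _uniform_disc(self.halt_u[:, :, k], self.halt_theta[:, :, k],
                            self.centers[tt], self.radii[tt])
        halt[mask] = pts[mask]


def _outcome_record(config: TrialConfig, trial_id: str, seed: int,
                    site_idx: int, time: float) -> dict:
    site = SITE_LABELS[site_idx] if site_idx >= 0 else None
    return {
        "trial_id": trial_id,
        "seed": seed,
        "condition": config.condition,
        "difficulty": config.difficulty,
        "n_participants": config.n_participants,
        "consensus_site": site,
        "consensus_time": None if site is None else float(time),
        "success": bool(site == config.correct_site),
    }


def _to_table(config: TrialConfig, trial_id: str, pos_log: np.ndarray,
              head_log: np.ndarray, end_tick: int) -> TrajectoryTable:
    n_sub = int(round(config.sample_rate))
    n_frames = int(end_tick) * n_sub + 1
    ts = np.arange(n_frames) / n_sub
    A = config.n_participants
    pids = config.participant_ids()
    rows = {
        "trial_id": np.repeat(trial_id, A * n_frames),
        "participant_id": np.repeat(pids, n_frames),
        "t": np.tile(ts, A),
        "x": pos_log[:, :n_frames, 0].astype(float).ravel(),
        "y": pos_log[:, :n_frames, 1].astype(float).ravel(),
        "heading": head_log[:, :n_frames].astype(float).ravel(),
        "informed": np.repeat(
            [pid in config.informed_ids for pid in pids], n_frames),
    }
    return TrajectoryTable(pd.DataFrame(rows), config)


def simulate_trial(config: TrialConfig, params: AgentParams, seed: int,
                   trial_id: str | None = None,
                   record: bool = True) -> tuple[TrajectoryTable | None, dict]:
    """Simulate one trial; deterministic given ``seed``.

    Returns the logged trajectory table (or ``None`` when ``record=False``)
    and the ground-truth outcome record.
    """
    trial_id = trial_id or f"trial_{seed}"
    eng = _BatchEngine(config, params, [seed], record=record)
    pos_log, head_log, c_site, c_time, end_tick = eng.run()
    outcome = _outcome_record(config, trial_id, seed, int(c_site[0]),
                              float(c_time[0]))
    table = None
    if record:
        table = _to_table(config, trial_id, pos_log[0], head_log[0],
                          int(end_tick[0]))
    return table, outcome


def trial_seed(master_seed: int, index: int) -> int:
    """Reproducible per-trial seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0])


def simulate_batch(configs: Sequence[TrialConfig], params: AgentParams,
                   n_per_cell: int, master_seed: int, record: bool = True,
                   batch_size: int = 500):
    """Simulate ``n_per_cell`` trials for every configuration cell.

    Returns ``(tables, manifest)`` where ``tables`` is a list of
    TrajectoryTables (empty when ``record=False``) aligned with the rows of
    the ``manifest`` DataFrame (trial id, per-trial seed, condition,
    difficulty, truth outcome).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    tables: list[TrajectoryTable] = []
    records: list[dict] = []
    idx = 0
    for config in configs:
        cell_seeds = [trial_seed(master_seed, idx + j) for j in range(n_per_cell)]
        cell_ids = [f"{config.condition}_{config.difficulty}_{idx + j:05d}"
                    for j in range(n_per_cell)]
        idx += n_per_cell
        for lo in range(0, n_per_cell, batch_size):
            chunk = slice(lo, min(lo + batch_size, n_per_cell))
            eng = _BatchEngine(config, params, cell_seeds[chunk], record=record)
            pos_log, head_log, c_site, c_time, end_tick = eng.run()
            for j, (tid, sd) in enumerate(zip(cell_ids[chunk], cell_seeds[chunk])):
                records.append(_outcome_record(config, tid, sd,
                                               int(c_site[j]), float(c_time[j])))
                if record:
                    tables.append(_to_table(config, tid, pos_log[j],
                                            head_log[j], int(end_tick[j])))
    manifest = pd.DataFrame(records)
    return tables, manifest


# ---------------------------------------------------------------------------
# single-agent decision step (same kernels as the batch engine, scalar shapes)

def agent_step(state: AgentState, social_counts: Mapping[str, int],
               params: AgentParams, config: TrialConfig,
               rng: np.random.Generator) -> AgentState:
    """Advance one agent by one 1-second decision tick.

    ``social_counts`` are per-site supporter counts over the *other*
    participants.  The returned state has updated target, occupancy clock
    and pose after one second of kinematics.
    """
    state = replace(state, perceived_radii=dict(state.perceived_radii),
                    explored=set(state.explored))
    counts = np.array([social_counts.get(lab, 0) for lab in SITE_LABELS],
                      dtype=float)
    centers = np.array([s.center for s in config.sites])
    radii = np.array([s.radius for s in config.sites])
    known = np.array([state.perceived_radii.get(lab) is not None
                      for lab in SITE_LABELS])
    perc = np.array([state.perceived_radii.get(lab) or 0.0
                     for lab in SITE_LABELS])
    correct = SITE_LABELS.index(config.correct_site)

    if state.current_target is None:
        if state.informed:
            _commit(state, correct, centers, radii, rng)
        elif known.any() and params.perception:
            score = np.where(known, perc + params.w_social * counts, -np.inf)
            _commit(state, int(score.argmax()), centers, radii, rng)
        else:
            d = np.linalg.norm(centers - np.array(state.position), axis=-1)
            d = np.where([lab in state.explored for lab in SITE_LABELS],
                         np.inf, d)
            if params.explore_policy == "nearest_unexplored":
                wp = int(d.argmin())
            else:
                unexp = [i for i, lab in enumerate(SITE_LABELS)
                         if lab not in state.explored]
                wp = unexp[int(rng.uniform() * len(unexp))] if unexp else 0
            state.explore_waypoint = tuple(centers[wp])
    else:
        own = SITE_LABELS.index(state.current_target)
        alt = counts.copy()
        alt[own] = -np.inf
        ds = float(alt.max() - counts[own])
        d = float(np.linalg.norm(np.array(state.position) - centers[own]))
        goal_now = np.array(state.halt_point or state.position)
        dg = goal_now - np.array(state.position)
        aligned = (np.hypot(*dg) <= _ARRIVE_TOL or state.occupancy_clock > 0
                   or abs(float(_wrap_angle(np.array(
                       math.atan2(dg[1], dg[0]) - state.heading)))) < HEADING_GATE)
        p = switch_probability(params, ds, d, state.occupancy_clock,
                               informed=state.informed) \
            if (aligned and state.commit_age >= params.refractory_s) else 0.0
        if (state.informed and params.informed_social_discount == 0.0
                and own == correct):
            p = 0.0
        if rng.uniform() < p:
            if params.tie_break == "random":
                r_eff = rng.uniform(size=4)
            else:
                r_eff = np.where(known, perc, -1e3)
            alt_score = counts * 1e6 + r_eff
            alt_score[own] = -np.inf
            _commit(state, int(alt_score.argmax()), centers, radii, rng)

    # one second of kinematics toward the halt point / waypoint
    goal = state.halt_point or state.explore_waypoint or state.position
    pos = np.array(state.position)[None, None, :]
    head = np.array([[state.heading]])
    goal_a = np.array(goal)[None, None, :]
    n_sub = int(round(config.sample_rate))
    for _ in range(n_sub):
        pos, head = _kinematic_substep(pos, head, goal_a, 1.0 / n_sub,
                                       config.speed, config.rot_rate,
                                       move_mask=np.ones((1, 1), dtype=bool))
    state.position = (float(pos[0, 0, 0]), float(pos[0, 0, 1]))
    state.heading = float(head[0, 0])
    state.commit_age += 1

    if state.current_target is not None:
        own = SITE_LABELS.index(state.current_target)
        at_halt = (state.halt_point is not None and
                   math.dist(state.position, state.halt_point) <= _ARRIVE_TOL)
        inside = math.dist(state.position, tuple(centers[own])) < radii[own]
        state.occupancy_clock = state.occupancy_clock + 1 if (at_halt and inside) else 0
    return state


def _commit(state: AgentState, site_idx: int, centers: np.ndarray,
            radii: np.ndarray, rng: np.random.Generator) -> None:
    state.current_target = SITE_LABELS[site_idx]
    state.commit_age = 0
    pt = _uniform_disc(np.array(rng.uniform()), np.array(rng.uniform()),
                       centers[site_idx], radii[site_idx])
    state.halt_point = (float(pt[0]), float(pt[1]))
    state.occupancy_clock = 0
    state.explore_waypoint = None
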