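"""End-to-end orchestration: simulate -> extract -> events -> score -> fit.

`run_pipeline` drives the whole chain from one experiment configuration
file and writes plain CSV tables plus a JSON run manifest (seeds, row
counts, file digests) into a report directory.  Every stochastic stage is
governed by the single master seed recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import CONDITIONS, DIFFICULTIES, TrialConfig, design_cells
from .events import build_events
from .metrics import metrics_table
from .models import (FitResult, ModelSpec, anova_type2, emm_pairwise,
                     fit_model, predicted_switch_curve)
from .opinions import opinion_series
from .outcomes import detect_consensus, outcomes_frame, score_trial, summarize
from .simulate import AgentParams, simulate_batch
from .trajectory import TrajectoryTable, resample_1hz

logger = logging.getLogger(__name__)


def trial_events(table: TrajectoryTable) -> tuple[pd.DataFrame, pd.DataFrame,
                                                  pd.DataFrame]:
    """Opinion series, per-second metrics and event table for one trial.

    Opinions are classified on the raw table (bin-start instants, velocities
    from the native sampling grid); covariates use the 1 Hz resample.
    """
    t1 = resample_1hz(table)
    series = opinion_series(table)
    mets = metrics_table(t1, series)
    events = build_events(series, mets, table.config)
    return series, mets, events


def dataset_events(tables: Iterable[TrajectoryTable]) -> pd.DataFrame:
    """Concatenated event table over many trials."""
    parts = [trial_events(t)[2] for t in tables]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


DEFAULT_EXPERIMENT = {
    "n_per_cell": 20,
    "master_seed": 20260101,
    "conditions": list(CONDITIONS),
    "difficulties": list(DIFFICULTIES),
    "n_participants": 8,
    "agent_params": {},
}


def load_experiment(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_EXPERIMENT)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown experiment keys: {sorted(unknown)}")
        cfg.update(user)
    if cfg["n_per_cell"] < 1:
        raise ValueError("n_per_cell must be >= 1")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(experiment_config: str | Path | None, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Run the full analysis chain; returns the report directory."""
    cfg = load_experiment(experiment_config)
    if seed is not None:
        cfg["master_seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = AgentParams(**cfg["agent_params"])
    cells = design_cells(cfg["conditions"], cfg["difficulties"],
                         n_participants=cfg["n_participants"])

    logger.info("simulating %d cells x %d trials", len(cells), cfg["n_per_cell"])
    tables, manifest = simulate_batch(cells, params, cfg["n_per_cell"],
                                      cfg["master_seed"])

    logger.info("scoring %d trials", len(tables))
    outs = []
    for table in tables:
        outs.append(score_trial(detect_consensus(table), table.config,
                                trial_id=table.trial_id))
    outcomes = outcomes_frame(outs)
    summary = summarize(outcomes)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    summary.to_csv(out / "outcome_summary.csv", index=False)

    logger.info("building events")
    events = dataset_events(tables)
    events.to_csv(out / "events.csv", index=False)

    written = {"outcomes.csv": len(outcomes), "outcome_summary.csv": len(summary),
               "events.csv": len(events)}

    # switch model, moving samples, global condition
    mov = events[(events["mode"] == "moving")
                 & (events["condition"] == "global")]
    if len(mov) and mov["switch"].nunique() > 1 \
            and mov["difficulty"].nunique() > 1:
        spec = ModelSpec("switch",
                         ("delta_social", "difficulty",
                          "delta_social:difficulty", "on_correct"),
                         random_intercepts=("participant_id",))
        fit = fit_model(mov, spec)
        _write_fit(out, "switch_moving_global", fit)
        curves = pd.concat([
            predicted_switch_curve(fit, np.arange(-10, 11),
                                   at={"difficulty": d})
            .assign(difficulty=d)
            for d in sorted(mov["difficulty"].unique())
        ])
        curves.to_csv(out / "switch_moving_global_curves.csv", index=False)
        written["switch_moving_global_curves.csv"] = len(curves)

    # spatiotemporal model, still samples, local condition
    still = events[(events["mode"] == "still")
                   & (events["condition"] == "local")]
    if len(still) and still["switch"].nunique() > 1:
        spec = ModelSpec("switch",
                         ("time_passed", "delta_social",
                          "I(delta_social**2)",
                          "time_passed:delta_social",
                          "time_passed:I(delta_social**2)"),
                         random_intercepts=("participant_id",))
        fit = fit_model(still, spec)
        _write_fit(out, "switch_still_local", fit, emm_factor=None)

    # informed vs uninformed approach-speed model
    inf_events = _informed_metrics(tables)
    if len(inf_events):
        spec = ModelSpec("approach_speed",
                         ("com_dist", "difficulty", "informed",
                          "com_dist:difficulty", "com_dist:informed",
                          "difficulty:informed",
                          "com_dist:difficulty:informed"),
                         random_intercepts=("participant_id",),
                         family="gaussian_identity")
        fit = fit_model(inf_events, spec)
        _write_fit(out, "approach_speed_informed", fit, emm_factor="difficulty")

    man = {
        "version": __version__,
        "experiment": cfg,
        "n_trials": len(tables),
        "row_counts": written,
        "per_trial_seeds": manifest[["trial_id", "seed"]]
        .set_index("trial_id")["seed"].to_dict(),
        "digests": {p.name: _digest(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(man, indent=2))
    _markdown_report(out, summary, written)
    return out


def _informed_metrics(tables: Sequence[TrajectoryTable]) -> pd.DataFrame:
    parts = []
    for table in tables:
        if table.config.condition != "informed_minority":
            continue
        t1 = resample_1hz(table)
        series = opinion_series(table)
        m = metrics_table(t1, series)
        m["difficulty"] = table.config.difficulty
        parts.append(m)
    if not parts:
        return pd.DataFrame()
    out = pd.concat(parts, ignore_index=True)
    return out.dropna(subset=["approach_speed", "com_dist"])


def _write_fit(out: Path, stem: str, fit: FitResult,
               emm_factor: str | None = "difficulty") -> None:
    fit.summary_frame().to_csv(out / f"{stem}_coefficients.csv")
    anova_type2(fit).to_csv(out / f"{stem}_anova.csv", index=False)
    if emm_factor is not None:
        try:
            emm_pairwise(fit, emm_factor).to_csv(
                out / f"{stem}_contrasts.csv", index=False)
        except ValueError:
            pass
    meta = {"converged": fit.converged, "fallback": fit.fallback,
            "vc": fit.vc, "loglike": fit.loglike, "n_dropped": fit.n_dropped}
    (out / f"{stem}_fitinfo.json").write_text(json.dumps(meta, indent=2))


def _markdown_report(out: Path, summary: pd.DataFrame, written: dict) -> None:
    lines = ["# Consensus arena pipeline report", "",
             "## Outcome summary", "",
             summary.to_markdown(index=False), "",
             "## Files", ""]
    lines += [f"- `{name}`: {n} rows" for name, n in written.items()]
    (out / "report.md").write_text("\n".join(lines) + "\n")
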