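"""End-to-end orchestration: per-trial metrics, scatter, and group summaries.

Learning trials receive latency, path length, path error, surface coverage,
average distance to final location, and idPhi. Probe trials additionally
receive the memory score and the trajectory distance to the block's last
learning trial. Response scatter is computed per (participant, setup, block)
across the four probe responses. Aggregation follows the trial ->
participant mean -> group mean order, with SEM = SD / sqrt(n) over
participants.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import efficiency_metrics as em
from . import memory_metrics as mm
from . import strategy_metrics as sm
from .io import read_session, write_metrics
from .types import (METRIC_VALUE_COLUMNS, ArenaConfig, MetricRecord, TrialMeta,
                    TrialTrajectory)

logger = logging.getLogger(__name__)

__all__ = [
    "trial_seed",
    "compute_trial_metrics",
    "compute_session_metrics",
    "run_pipeline",
    "summarize",
    "export_model_table",
]


def trial_seed(global_seed: int, meta: TrialMeta) -> int:
    """Stable per-trial RNG seed derived from the global seed and trial identity."""
    key = f"{meta.participant_id}|{meta.setup}|{meta.block}|{meta.trial_index}"
    return int(np.random.SeedSequence(
        [int(global_seed), zlib.crc32(key.encode())]).generate_state(1)[0] % 2**31)


def compute_trial_metrics(meta: TrialMeta, traj: TrialTrajectory,
                          arena: ArenaConfig, seed: int,
                          last_learning: Optional[TrialTrajectory] = None,
                          ) -> MetricRecord:
    """All per-trial metrics for one trial.

    ``seed`` is the global analysis seed; the memory score's reference points
    are drawn from a per-trial substream so trials are reproducible yet
    uncorrelated. ``last_learning`` is required for a probe trial's
    trajectory distance; without it the metric is missing (logged).
    """
    rec = MetricRecord(
        participant_id=meta.participant_id, group=meta.group, setup=meta.setup,
        block=meta.block, trial_type=meta.trial_type,
        trial_index=meta.trial_index, start_angle=meta.start_angle,
        probe_rotation=meta.probe_rotation,
        target_x=meta.target_location[0], target_y=meta.target_location[1],
        final_x=float(traj.final_location[0]),
        final_y=float(traj.final_location[1]),
    )
    rec.latency = em.latency(traj)
    rec.path_length = em.path_length(traj.positions)
    rec.path_error = em.path_error(traj)
    rec.surface_coverage = em.surface_coverage(traj, arena)
    rec.avg_distance_to_final = sm.avg_distance_to_final(traj)
    rec.idphi = sm.initial_angular_velocity(traj, arena)
    if meta.trial_type == "probe":
        rec.memory_score = mm.memory_score(
            traj.final_location, meta.target_location, arena,
            trial_seed(seed, meta)).score
        if last_learning is None:
            logger.warning("%s: no learning trial in block; "
                           "trajectory_distance missing", meta.label())
        else:
            rec.trajectory_distance = sm.trajectory_distance(
                last_learning, traj, arena)
    return rec


def compute_session_metrics(session: Sequence[tuple[TrialMeta, TrialTrajectory]],
                            arena: ArenaConfig, seed: int,
                            ) -> tuple[list[MetricRecord], pd.DataFrame]:
    """Metrics for every trial of a session plus per-block probe scatter."""
    last_learning: dict = {}
    records = []
    finals: dict = {}
    for meta, traj in session:
        key = (meta.participant_id, meta.setup, meta.block)
        if meta.trial_type == "learning":
            last_learning[key] = traj
        records.append(compute_trial_metrics(
            meta, traj, arena, seed, last_learning.get(key)))
        if meta.trial_type == "probe":
            finals.setdefault(key + (meta.group,), []).append(traj.final_location)
    scatter_rows = []
    for (pid, setup, block, group), pts in finals.items():
        scatter_rows.append({
            "participant_id": pid, "group": group, "setup": setup,
            "block": block, "n_probes": len(pts),
            "scatter": mm.final_location_scatter(pts, allow_fewer=True),
        })
    return records, pd.DataFrame(scatter_rows)


def _discover_sessions(input_dir: Path) -> list[tuple[Path, Path]]:
    pairs = []
    for tf in sorted(input_dir.glob("*_trajectory.csv")):
        mf = tf.with_name(tf.name.replace("_trajectory.csv", "_meta.csv"))
        if not mf.exists():
            raise FileNotFoundError(f"no metadata file for {tf.name}")
        pairs.append((tf, mf))
    if not pairs:
        raise FileNotFoundError(f"no *_trajectory.csv files in {input_dir}")
    return pairs


def run_pipeline(input_dir: str | Path, arena: ArenaConfig,
                 out_dir: str | Path, seed: int = 0,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute metrics for every session in ``input_dir`` and aggregate.

    Writes ``metrics.csv`` (one row per trial), ``scatter.csv`` (per
    participant x setup x block), ``summary.csv`` (group x setup x trial_type
    per metric) and a run manifest to ``out_dir``; returns the metric and
    summary tables.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_records: list[MetricRecord] = []
    scatter_parts = []
    pairs = _discover_sessions(input_dir)
    for tf, mf in pairs:
        session = read_session(tf, mf, arena)
        recs, scatter = compute_session_metrics(session, arena, seed)
        all_records += recs
        scatter_parts.append(scatter)
    metrics = pd.DataFrame([r.to_dict() for r in all_records])
    scatter = pd.concat(scatter_parts, ignore_index=True)
    summary = summarize(metrics, scatter)
    write_metrics(all_records, out_dir / "metrics.csv")
    scatter.to_csv(out_dir / "scatter.csv", index=False, float_format="%.17g")
    summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.17g")
    manifest = {
        "seed": seed,
        "arena": {"center": list(arena.center), "radius": arena.radius,
                  "grid_n": arena.grid_n,
                  "n_reference_points": arena.n_reference_points,
                  "idphi_window": arena.idphi_window,
                  "filter_cutoff": arena.filter_cutoff},
        "inputs": [str(tf) for tf, _ in pairs],
        "n_trials": len(metrics),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return metrics, summary


def summarize(metrics: pd.DataFrame, scatter: Optional[pd.DataFrame] = None,
              *, pooled: bool = False) -> pd.DataFrame:
    """Group x setup x trial_type mean, SEM and n for every metric.

    Default aggregation is trial -> participant mean -> group mean with
    SEM = SD / sqrt(n participants); ``pooled=True`` instead pools trials
    directly (n = number of trials).
    """
    long = metrics.melt(
        id_vars=["participant_id", "group", "setup", "trial_type"],
        value_vars=METRIC_VALUE_COLUMNS, var_name="metric")
    long = long.dropna(subset=["value"])
    if scatter is not None and len(scatter):
        sc = scatter.rename(columns={"scatter": "value"})
        sc["trial_type"] = "probe"
        sc["metric"] = "scatter"
        long = pd.concat([long, sc[long.columns]], ignore_index=True)
    if not pooled:
        long = (long.groupby(["group", "setup", "trial_type", "metric",
                              "participant_id"], as_index=False)["value"].mean())
    agg = (long.groupby(["group", "setup", "trial_type", "metric"])["value"]
           .agg(mean="mean", sd="std", n="count").reset_index())
    agg["sem"] = agg["sd"] / np.sqrt(agg["n"])
    return agg[["group", "setup", "trial_type", "metric", "mean", "sem", "n"]]


def export_model_table(metrics: pd.DataFrame,
                       participants: Optional[pd.DataFrame] = None,
                       *, log_transform: bool = False) -> pd.DataFrame:
    """Analysis-ready long table: one row per participant x setup x metric.

    Values are participant means over the trials where the metric is defined;
    rows for entirely-missing metrics are omitted (count logged). Joins
    participant covariates (session order, sex, age, education) when a
    participants table is given — the shape expected by an external
    mixed-model fit with group and setup as fixed effects and participant as
    a random effect.

    With ``log_transform``, a metric whose distribution has skewness outside
    [-2, 2] or excess kurtosis outside [-7, 7] is log-transformed
    (``log(x + 1e-9)``, values shifted above zero first if needed) and
    flagged in the ``transformed`` column.
    """
    long = metrics.melt(
        id_vars=["participant_id", "group", "setup"],
        value_vars=METRIC_VALUE_COLUMNS, var_name="metric")
    n_total = len(long)
    long = long.dropna(subset=["value"])
    table = (long.groupby(["participant_id", "group", "setup", "metric"],
                          as_index=False)["value"].mean())
    n_expected = (metrics[["participant_id", "setup"]].drop_duplicates().shape[0]
                  * len(METRIC_VALUE_COLUMNS))
    if len(table) < n_expected:
        logger.info("export_model_table: %d participant x setup x metric cells "
                    "missing (of %d)", n_expected - len(table), n_expected)
    table["transformed"] = False
    if log_transform:
        for metric, sub in table.groupby("metric"):
            v = sub["value"].to_numpy()
            if len(v) < 3:
                continue
            skew = _stats.skew(v)
            kurt = _stats.kurtosis(v)  # Fisher: normal -> 0
            if abs(skew) > 2 or kurt < -7 or kurt > 7:
                shift = -v.min() if v.min() <= 0 else 0.0
                table.loc[sub.index, "value"] = np.log(v + shift + 1e-9)
                table.loc[sub.index, "transformed"] = True
    if participants is not None:
        table = table.merge(
            participants.rename(columns={"participant": "participant_id"}),
            on="participant_id", how="left", suffixes=("", "_cov"))
    return table
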