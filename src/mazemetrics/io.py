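"""Readers and writers for trajectory sessions and metric tables.

No standard on-disk format exists for navigation logs, so the package fixes a
plain-CSV dialect:

* trajectory file — long table with one row per sample, columns
  ``participant,setup,block,trial_type,trial_index,t,x,y`` plus either a
  ``yaw`` column (radians) or quaternion columns ``qw,qx,qy,qz``;
* metadata file — one row per trial with columns ``participant,group,setup,
  block,trial_type,trial_index,start_angle,probe_rotation,target_x,target_y``
  and optionally ``sampling_rate``.

Metric tables are tidy CSV, one row per trial, with a stable column order and
empty cells (never zero) for metrics undefined on a trial type.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .signal_prep import quaternion_to_yaw
from .types import (METRIC_COLUMNS, ArenaConfig, MetricRecord, TrialMeta,
                    TrialTrajectory, ValidationError)

__all__ = ["read_session", "write_session", "write_metrics", "read_metrics"]

_TRIAL_KEY = ["participant", "setup", "block", "trial_type", "trial_index"]
_QUAT_COLS = ["qw", "qx", "qy", "qz"]


def _trial_label(key) -> str:
    participant, setup, block, trial_type, trial_index = key
    return (f"participant={participant} setup={setup} block={block} "
            f"{trial_type} trial {trial_index}")


def read_session(trajectory_file: str | Path, meta_file: str | Path,
                 arena: ArenaConfig, *, axis_map=None,
                 axis_convention: str = "z_up",
                 ) -> list[tuple[TrialMeta, TrialTrajectory]]:
    """Load one session's trials, validated against all invariants.

    Parameters
    ----------
    axis_map : (2, 2) array, optional
        Linear map applied to the raw (x, y) columns, as an escape hatch for
        recordings whose axis conventions differ from the package's
        (arena-centered, right-handed). Default: identity.
    axis_convention : {"z_up", "unity_y_up"}
        Convention used when orientation comes as quaternion columns.

    Returns
    -------
    list of (TrialMeta, TrialTrajectory), ordered as in the metadata file.
    """
    traj_df = pd.read_csv(trajectory_file, float_precision="round_trip")
    meta_df = pd.read_csv(meta_file, float_precision="round_trip")
    missing = [c for c in _TRIAL_KEY + ["t", "x", "y"] if c not in traj_df.columns]
    if missing:
        raise ValidationError(f"trajectory file missing columns {missing}")
    has_yaw = "yaw" in traj_df.columns
    has_quat = all(c in traj_df.columns for c in _QUAT_COLS)
    if not (has_yaw or has_quat):
        raise ValidationError(
            "trajectory file needs a 'yaw' column or quaternion columns qw,qx,qy,qz")

    groups = {key: g for key, g in traj_df.groupby(_TRIAL_KEY, sort=False)}
    out: list[tuple[TrialMeta, TrialTrajectory]] = []
    for row in meta_df.itertuples(index=False):
        key = (row.participant, row.setup, int(row.block), row.trial_type,
               int(row.trial_index))
        label = _trial_label(key)
        if key not in groups:
            raise ValidationError(f"{label}: no trajectory rows found")
        g = groups.pop(key)
        t = g["t"].to_numpy(dtype=float)
        xy = g[["x", "y"]].to_numpy(dtype=float)
        if axis_map is not None:
            xy = xy @ np.asarray(axis_map, dtype=float).T
        if has_yaw:
            yaw = g["yaw"].to_numpy(dtype=float)
        else:
            try:
                yaw = quaternion_to_yaw(g[_QUAT_COLS].to_numpy(dtype=float),
                                        axis_convention)
            except ValueError as exc:
                raise ValidationError(f"{label}: {exc}") from exc
        if "sampling_rate" in meta_df.columns and np.isfinite(row.sampling_rate):
            fs = float(row.sampling_rate)
        else:
            fs = 1.0 / float(np.median(np.diff(t)))
        traj = TrialTrajectory(t, xy, yaw, fs).validate(arena, label=label)
        probe_rotation = None
        if "probe_rotation" in meta_df.columns and not pd.isna(row.probe_rotation):
            probe_rotation = float(row.probe_rotation)
        meta = TrialMeta(
            participant_id=str(row.participant), group=str(row.group),
            setup=str(row.setup), block=int(row.block),
            trial_type=str(row.trial_type), trial_index=int(row.trial_index),
            start_angle=float(row.start_angle),
            target_location=(float(row.target_x), float(row.target_y)),
            probe_rotation=probe_rotation,
            final_location=tuple(traj.final_location),
        ).validate(arena)
        out.append((meta, traj))
    if groups:
        stray = _trial_label(next(iter(groups)))
        raise ValidationError(f"trajectory rows without metadata: {stray}")
    return out


def write_session(trials: Sequence[tuple[TrialMeta, TrialTrajectory]],
                  trajectory_file: str | Path, meta_file: str | Path) -> None:
    """Serialize trials to the package's trajectory + metadata CSV dialect."""
    traj_parts = []
    meta_rows = []
    for meta, traj in trials:
        n = traj.n_samples
        traj_parts.append(pd.DataFrame({
            "participant": [meta.participant_id] * n,
            "setup": [meta.setup] * n,
            "block": [meta.block] * n,
            "trial_type": [meta.trial_type] * n,
            "trial_index": [meta.trial_index] * n,
            "t": traj.timestamps,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "yaw": traj.yaw,
        }))
        meta_rows.append({
            "participant": meta.participant_id, "group": meta.group,
            "setup": meta.setup, "block": meta.block,
            "trial_type": meta.trial_type, "trial_index": meta.trial_index,
            "start_angle": meta.start_angle,
            "probe_rotation": meta.probe_rotation,
            "target_x": meta.target_location[0],
            "target_y": meta.target_location[1],
            "sampling_rate": traj.sampling_rate,
        })
    pd.concat(traj_parts, ignore_index=True).to_csv(
        trajectory_file, index=False, float_format="%.17g")
    pd.DataFrame(meta_rows).to_csv(meta_file, index=False, float_format="%.17g")


def write_metrics(records: Sequence[MetricRecord] | pd.DataFrame,
                  out: str | Path) -> Path:
    """Write a tidy metric table, one row per trial, stable column order.

    Missing metrics (undefined for the trial type) become empty fields and
    round-trip back as NaN.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        if len(records) == 0:
            raise ValueError("records must be non-empty")
        df = pd.DataFrame([r.to_dict() for r in records])
    df = df.reindex(columns=METRIC_COLUMNS)
    out = Path(out)
    df.to_csv(out, index=False, float_format="%.17g", na_rep="")
    return out


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read back a metric table written by :func:`write_metrics`."""
    return pd.read_csv(path, float_precision="round_trip").reindex(columns=METRIC_COLUMNS)
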