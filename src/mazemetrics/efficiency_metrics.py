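"""Navigation efficiency: latency, path length, path error, surface coverage,
and per-cell presence-probability maps.

Path error is the percent excess of the traveled path over the straight
start-to-final segment; surface coverage is a bounding-box estimate of the
fraction of arena area traversed. The coverage formula uses the full
bounding-box widths (so a trajectory spanning the arena's bounding square
yields 400%); a semi-axis ellipse variant is available behind ``semi_axes``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .memory_metrics import _bin_points
from .types import ArenaConfig, TrialTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceMap",
    "latency",
    "path_length",
    "path_error",
    "surface_coverage",
    "presence_map",
]


@dataclass(frozen=True)
class PresenceMap:
    """Per-cell probability that a trial's path visited that cell."""

    grid: np.ndarray  # (grid_n, grid_n) in [0, 1]; grid[i, j] = x-bin i, y-bin j
    bounds: tuple[float, float, float, float]
    n_trials: int


def latency(trial: TrialTrajectory) -> float:
    """Trial duration in seconds: last timestamp minus first."""
    return float(trial.timestamps[-1] - trial.timestamps[0])


def path_length(positions) -> float:
    """Total polyline length: sum of Euclidean segment lengths."""
    pts = np.asarray(positions, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def path_error(trial: TrialTrajectory, *, tol: float = 1e-6) -> float:
    """Percent excess path length over the straight start-to-final segment.

    Zero for a perfectly straight path; unbounded above. If start and final
    coincide (ideal length below ``tol``) the metric is undefined and NaN is
    returned with a logged note.
    """
    ideal = float(np.linalg.norm(trial.final_location - trial.start_location))
    if ideal < tol:
        logger.info("path_error undefined: start equals final location")
        return float("nan")
    actual = path_length(trial.positions)
    return 100.0 * (actual - ideal) / ideal


def surface_coverage(trial: TrialTrajectory, arena: ArenaConfig,
                     *, semi_axes: bool = False) -> float:
    """Bounding-box estimate of the percent of arena area covered.

    Default: ``pi * |x_min - x_max| * |y_min - y_max| / (pi R^2) * 100`` with
    the full box widths, so values can exceed 100 (a full bounding square
    gives 400). ``semi_axes=True`` instead uses the inscribed ellipse with
    semi-axes equal to half the widths, capping a full box at 100.
    """
    x = trial.positions[:, 0]
    y = trial.positions[:, 1]
    wx = float(np.ptp(x))
    wy = float(np.ptp(y))
    if semi_axes:
        wx, wy = wx / 2.0, wy / 2.0
    return 100.0 * (np.pi * wx * wy) / (np.pi * arena.radius ** 2)


def presence_map(trials: Sequence[TrialTrajectory], arena: ArenaConfig) -> PresenceMap:
    """Fraction of trials whose path visited each cell of the arena grid.

    Visitation is sample-based: a cell counts for a trial if any sample falls
    in it. At 60-90 Hz and <= 1.4 m/s a sample step cannot skip a grid cell
    (0.38 m at the default resolution), so segment intersection is unnecessary.
    """
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    counts = np.zeros((arena.grid_n, arena.grid_n))
    for traj in trials:
        visited = np.zeros_like(counts, dtype=bool)
        ix, iy = _bin_points(traj.positions, arena)
        visited[ix, iy] = True
        counts += visited
    cx, cy = arena.center
    R = arena.radius
    return PresenceMap(grid=counts / len(trials),
                       bounds=(cx - R, cx + R, cy - R, cy + R),
                       n_trials=len(trials))
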