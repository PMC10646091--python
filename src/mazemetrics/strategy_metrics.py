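"""Navigation-strategy measures: search accuracy, landmark use, path replication.

* ``avg_distance_to_final`` — mean distance of all samples to the response
  location; low values indicate focused search near the final location.
* ``initial_angular_velocity`` (idPhi) — mean absolute per-sample yaw change
  over the first seconds of a trial; proxies landmark scanning / vicarious
  trial-and-error.
* ``trajectory_distance`` — rotation-aligned, length-normalized square-root
  DTW cost between the last learning trajectory and a probe trajectory; low
  values indicate egocentric route replay.

The dynamic-time-warping dynamic program (squared-Euclidean local cost,
symmetric unit-weight steps, full boundary alignment) is implemented here and
verified in the test suite against exhaustive warping-path enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_prep import preprocess_yaw
from .types import ArenaConfig, TrialTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "DtwResult",
    "avg_distance_to_final",
    "initial_angular_velocity",
    "dtw_squared",
    "trajectory_distance",
    "rotate_about_center",
]


def _dtw_cost_matrix_py(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m, n = a.shape[0], b.shape[0]
    D = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            c = 0.0
            for k in range(a.shape[1]):
                d = a[i, k] - b[j, k]
                c += d * d
            if i == 0 and j == 0:
                D[i, j] = c
            elif i == 0:
                D[i, j] = c + D[i, j - 1]
            elif j == 0:
                D[i, j] = c + D[i - 1, j]
            else:
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = c + best
    return D


try:  # JIT-compile the quadratic DP; trajectories reach a few thousand samples
    from numba import njit

    _dtw_cost_matrix = njit(cache=True)(_dtw_cost_matrix_py)
except ImportError:  # pragma: no cover
    _dtw_cost_matrix = _dtw_cost_matrix_py


@dataclass(frozen=True)
class DtwResult:
    """Full-boundary DTW alignment between two point sequences."""

    cost: float  # accumulated squared-Euclidean cost
    path: list  # (i, j) index pairs, 0-based, from (0, 0) to (m-1, n-1)
    m: int
    n: int

    @property
    def normalized_distance(self) -> float:
        """sqrt(cost / max(m, n)) — cost per minimal warping-path length."""
        return float(np.sqrt(self.cost / max(self.m, self.n)))


def dtw_squared(a, b) -> DtwResult:
    """Dynamic time warping with squared-Euclidean local cost.

    Classic dynamic program over all monotone warping paths with steps
    (1,0), (0,1), (1,1), unit weights and full boundary conditions; the
    returned cost is the minimum accumulated cost over all admissible paths.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("both sequences must contain at least one point")
    if a.shape[1] != b.shape[1]:
        raise ValueError("sequences must have the same point dimension")
    D = _dtw_cost_matrix(a, b)
    # backtrack the optimal alignment
    i, j = a.shape[0] - 1, b.shape[0] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            steps = ((D[i - 1, j - 1], i - 1, j - 1),
                     (D[i - 1, j], i - 1, j),
                     (D[i, j - 1], i, j - 1))
            _, i, j = min(steps)
        path.append((i, j))
    path.reverse()
    return DtwResult(cost=float(D[-1, -1]), path=path, m=a.shape[0], n=b.shape[0])


def avg_distance_to_final(trial: TrialTrajectory, arena: ArenaConfig | None = None,
                          *, normalize: bool = False) -> float:
    """Mean Euclidean distance of every sample to the trial's final location.

    With ``normalize`` the result is divided by the arena diameter.
    """
    d = np.linalg.norm(trial.positions - trial.final_location, axis=1)
    out = float(d.mean())
    if normalize:
        if arena is None:
            raise ValueError("normalize=True requires an ArenaConfig")
        out /= 2.0 * arena.radius
    return out


def initial_angular_velocity(trial: TrialTrajectory, arena: ArenaConfig,
                             *, per_second: bool = False,
                             preprocess: bool = True) -> float:
    """idPhi: mean absolute yaw change per sample step over the initial window.

    The yaw channel is unwrapped and zero-phase low-pass filtered
    (``arena.filter_cutoff``), then restricted to samples with timestamp
    within ``arena.idphi_window`` seconds of trial onset (the whole trial,
    with a logged note, if it is shorter). The default unit is radians per
    sample step, exactly ``sum |yaw_i - yaw_{i+1}| / n`` over the n in-window
    differences; ``per_second=True`` multiplies by the sampling rate so the
    60 Hz and 90 Hz setups are on a common rad/s scale.
    """
    yaw = (preprocess_yaw(trial.yaw, trial.sampling_rate, arena.filter_cutoff)
           if preprocess else np.asarray(trial.yaw, dtype=float))
    t = trial.timestamps
    mask = t < t[0] + arena.idphi_window
    if mask.all() and t[-1] - t[0] < arena.idphi_window:
        logger.info("trial shorter than the %.3g s idPhi window; using all samples",
                    arena.idphi_window)
    yaw_w = yaw[mask]
    if len(yaw_w) < 2:
        return float("nan")
    idphi = float(np.abs(np.diff(yaw_w)).mean())
    return idphi * trial.sampling_rate if per_second else idphi


def rotate_about_center(positions: np.ndarray, angle: float,
                        center) -> np.ndarray:
    """Rotate points counterclockwise by ``angle`` radians about ``center``."""
    c, s = np.cos(angle), np.sin(angle)
    rel = np.asarray(positions, dtype=float) - np.asarray(center, dtype=float)
    return (rel @ np.array([[c, s], [-s, c]])) + np.asarray(center, dtype=float)


def _align_to_zero_angle(traj: TrialTrajectory, arena: ArenaConfig,
                         label: str, tol: float = 1e-9) -> np.ndarray:
    start = traj.start_location - arena.center_array
    r = float(np.linalg.norm(start))
    if r < tol:
        raise ValueError(
            f"{label}: start at the arena center; rotation alignment undefined")
    angle = float(np.arctan2(start[1], start[0]))
    return rotate_about_center(traj.positions, -angle, arena.center)


def trajectory_distance(last_learning: TrialTrajectory, probe: TrialTrajectory,
                        arena: ArenaConfig) -> float:
    """Rotation-aligned, normalized DTW distance between two trajectories.

    Each trajectory is rotated about the arena center by the angle that maps
    its first sample onto the zero-angle ray (radii preserved), removing the
    designed probe-start rotation; the aligned paths are then compared with
    squared-cost DTW and the accumulated cost normalized by the minimal
    warping-path length: ``sqrt(cost / max(m, n))``. A probe identical to the
    learning path up to a rotation about the center scores 0.
    """
    a = _align_to_zero_angle(last_learning, arena, "learning trial")
    b = _align_to_zero_angle(probe, arena, "probe trial")
    return dtw_squared(a, b).normalized_distance
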