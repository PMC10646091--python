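"""Spatial-memory performance: memory score, response scatter, final-location maps.

The memory score is the percent rank of the response-to-target distance
against locations drawn uniformly over the arena disk: 100 means the response
coincides with the target, 50 is chance-level responding, and values below 50
indicate a systematic bias away from the target. A closed-form oracle based
on circle-circle intersection areas is provided alongside the Monte-Carlo
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .types import ArenaConfig, TrialMeta, TrialTrajectory

__all__ = [
    "MemoryScoreResult",
    "FinalLocationMap",
    "sample_uniform_disk",
    "memory_score",
    "memory_score_analytic",
    "final_location_scatter",
    "final_location_map",
]


@dataclass(frozen=True)
class MemoryScoreResult:
    """Monte-Carlo memory score for a single probe response."""

    score: float  # percent in [0, 100]
    response_distance: float  # meters, |final - target|
    n_reference: int
    seed: int


@dataclass(frozen=True)
class FinalLocationMap:
    """Percentage of probe responses falling in each cell of an arena grid."""

    grid: np.ndarray  # (grid_n, grid_n), grid[i, j] = x-bin i, y-bin j
    bounds: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)


def sample_uniform_disk(n: int, arena: ArenaConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points uniformly over the arena disk (r = R*sqrt(u))."""
    r = arena.radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    return arena.center_array + np.column_stack((r * np.cos(theta), r * np.sin(theta)))


def memory_score(final, target, arena: ArenaConfig, seed: int,
                 n_reference: Optional[int] = None) -> MemoryScoreResult:
    """Percent rank of the response distance among uniform reference locations.

    Draws ``n_reference`` (default ``arena.n_reference_points``) locations
    uniformly over the arena disk with a seeded generator and returns
    ``100 - 100 * #{reference closer to target than final} / n_reference``.
    Ties (reference exactly as far as the response) do not count against the
    score: only strictly closer locations do. Deterministic given the seed.
    """
    n = arena.n_reference_points if n_reference is None else int(n_reference)
    if n < 1:
        raise ValueError("n_reference must be >= 1")
    final = np.asarray(final, dtype=float)
    target = np.asarray(target, dtype=float)
    d_resp = float(np.linalg.norm(final - target))
    rng = np.random.default_rng(seed)
    ref = sample_uniform_disk(n, arena, rng)
    d_ref = np.linalg.norm(ref - target, axis=1)
    closer = int(np.count_nonzero(d_ref < d_resp))
    return MemoryScoreResult(score=100.0 - 100.0 * closer / n,
                             response_distance=d_resp, n_reference=n, seed=seed)


def _lens_area(D: float, r: float, R: float) -> float:
    """Area of intersection of two disks with radii r, R and center distance D."""
    if r <= 0.0 or R <= 0.0:
        return 0.0
    if D >= r + R:
        return 0.0
    if D <= abs(R - r):
        rr = min(r, R)
        return np.pi * rr * rr
    a1 = np.arccos(np.clip((D * D + r * r - R * R) / (2.0 * D * r), -1.0, 1.0))
    a2 = np.arccos(np.clip((D * D + R * R - r * r) / (2.0 * D * R), -1.0, 1.0))
    kern = ((-D + r + R) * (D + r - R) * (D - r + R) * (D + r + R))
    return r * r * a1 + R * R * a2 - 0.5 * np.sqrt(max(kern, 0.0))


def memory_score_analytic(final, target, arena: ArenaConfig) -> float:
    """Exact expected memory score under uniform reference sampling.

    The Monte-Carlo score estimates ``100 * (1 - A/(pi R^2))`` where ``A`` is
    the area of the disk of radius ``|final - target|`` centered on the
    target, intersected with the arena disk. This computes that area in
    closed form.
    """
    final = np.asarray(final, dtype=float)
    target = np.asarray(target, dtype=float)
    d = float(np.linalg.norm(final - target))
    c = float(np.linalg.norm(target - arena.center_array))
    area = _lens_area(c, d, arena.radius)
    return 100.0 * (1.0 - area / (np.pi * arena.radius ** 2))


def final_location_scatter(finals: Sequence, arena: Optional[ArenaConfig] = None,
                           *, normalize: bool = False,
                           allow_fewer: bool = False) -> float:
    """Mean pairwise distance among a block's probe responses.

    With the standard four responses this is the mean of the C(4,2) = 6
    pairwise Euclidean distances. Fewer points are accepted only with
    ``allow_fewer`` (averaging over the available pairs); fewer than two
    points give NaN (undefined). With ``normalize`` the result is divided by
    the arena diameter.
    """
    pts = np.asarray(finals, dtype=float).reshape(-1, 2)
    if len(pts) != 4 and not allow_fewer:
        raise ValueError(f"expected 4 final locations, got {len(pts)} "
                         "(pass allow_fewer=True to accept)")
    if len(pts) < 2:
        return float("nan")
    scatter = float(pdist(pts).mean())
    if normalize:
        if arena is None:
            raise ValueError("normalize=True requires an ArenaConfig")
        scatter /= 2.0 * arena.radius
    return scatter


def _grid_edges(arena: ArenaConfig) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = arena.center
    R = arena.radius
    return (np.linspace(cx - R, cx + R, arena.grid_n + 1),
            np.linspace(cy - R, cy + R, arena.grid_n + 1))


def _bin_points(points: np.ndarray, arena: ArenaConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cell indices (ix, iy) of points on the arena grid, edge-inclusive."""
    xe, ye = _grid_edges(arena)
    ix = np.clip(np.searchsorted(xe, points[:, 0], side="right") - 1, 0, arena.grid_n - 1)
    iy = np.clip(np.searchsorted(ye, points[:, 1], side="right") - 1, 0, arena.grid_n - 1)
    return ix, iy


def final_location_map(trials: Sequence[tuple[TrialMeta, TrialTrajectory]],
                       arena: ArenaConfig) -> FinalLocationMap:
    """Bin probe-trial final locations into percentages on the arena grid.

    Each cell holds ``100 * (responses in cell) / (number of trials)``; the
    cells therefore sum to 100.
    """
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    finals = np.array([traj.final_location for _, traj in trials], dtype=float)
    grid = np.zeros((arena.grid_n, arena.grid_n))
    ix, iy = _bin_points(finals, arena)
    np.add.at(grid, (ix, iy), 100.0 / len(trials))
    cx, cy = arena.center
    R = arena.radius
    return FinalLocationMap(grid=grid, bounds=(cx - R, cx + R, cy - R, cy + R))
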