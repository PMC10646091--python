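"""Domain types for water-maze trajectory analysis.

Coordinate conventions: the arena is a circle in a Cartesian plane with the
arena center at the origin by default, units in (virtual) meters, and yaw in
radians measured counterclockwise from the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ArenaConfig",
    "TrialTrajectory",
    "TrialMeta",
    "MetricRecord",
    "ValidationError",
    "METRIC_COLUMNS",
]


class ValidationError(ValueError):
    """Raised when an input violates a trajectory or metadata invariant."""


@dataclass(frozen=True)
class ArenaConfig:
    """Circular arena geometry and analysis parameters.

    Parameters
    ----------
    center : (float, float)
        Arena center in meters.
    radius : float
        Arena radius in meters. The virtual arena used 3.8 m.
    grid_n : int
        Resolution of presence / final-location grids (``grid_n x grid_n``
        cells covering the bounding square ``[-R, R]^2`` around the center).
    n_reference_points : int
        Number of uniform reference locations drawn for the Monte-Carlo
        memory score.
    idphi_window : float
        Initial time window, in seconds, over which the initial angular
        velocity (idPhi) is computed.
    filter_cutoff : float
        Low-pass cutoff frequency (Hz) applied to the yaw channel.
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 3.8
    grid_n: int = 20
    n_reference_points: int = 1000
    idphi_window: float = 5.0
    filter_cutoff: float = 6.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError("arena radius must be positive")
        if self.grid_n < 1:
            raise ValidationError("grid_n must be >= 1")
        if self.n_reference_points < 1:
            raise ValidationError("n_reference_points must be >= 1")
        if not self.idphi_window > 0:
            raise ValidationError("idphi_window must be positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "center": list(self.center),
            "radius": self.radius,
            "grid_n": self.grid_n,
            "n_reference_points": self.n_reference_points,
            "idphi_window": self.idphi_window,
            "filter_cutoff": self.filter_cutoff,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArenaConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["center"] = tuple(payload.get("center", (0.0, 0.0)))
        return cls(**payload)


@dataclass
class TrialTrajectory:
    """One trial's navigation time series.

    Attributes
    ----------
    timestamps : ndarray, shape (n,)
        Seconds, strictly increasing.
    positions : ndarray, shape (n, 2)
        Arena-centered Cartesian x, y in meters.
    yaw : ndarray, shape (n,)
        Heading in radians, counterclockwise from +x.
    sampling_rate : float
        Nominal sampling rate in Hz (60 stationary, 90 mobile).
    """

    timestamps: np.ndarray
    positions: np.ndarray
    yaw: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)

    def validate(self, arena: ArenaConfig, *, wall_tol: float = 1e-6,
                 label: str = "trial") -> "TrialTrajectory":
        """Check all invariants, raising :class:`ValidationError` naming the trial."""
        n = len(self.timestamps)
        if n < 2:
            raise ValidationError(f"{label}: needs >= 2 samples, got {n}")
        if self.positions.shape != (n, 2):
            raise ValidationError(
                f"{label}: positions shape {self.positions.shape} does not match "
                f"{n} timestamps")
        if len(self.yaw) != n:
            raise ValidationError(
                f"{label}: yaw length {len(self.yaw)} does not match {n} timestamps")
        dt = np.diff(self.timestamps)
        if not np.all(dt > 0):
            bad = int(np.argmin(dt > 0))
            raise ValidationError(
                f"{label}: timestamps not strictly increasing at row {bad + 1}")
        r = np.linalg.norm(self.positions - arena.center_array, axis=1)
        if np.any(r > arena.radius + wall_tol):
            bad = int(np.argmax(r > arena.radius + wall_tol))
            raise ValidationError(
                f"{label}: position at row {bad} lies {r[bad]:.4f} m from center, "
                f"outside radius {arena.radius} m")
        return self

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def final_location(self) -> np.ndarray:
        """Last position sample — the response location (button press)."""
        return self.positions[-1]

    @property
    def start_location(self) -> np.ndarray:
        return self.positions[0]


GROUPS = ("MTLR", "control")
SETUPS = ("stationary", "mobile")
TRIAL_TYPES = ("learning", "probe", "baseline")


@dataclass
class TrialMeta:
    """Identifiers and design variables for one trial."""

    participant_id: str
    group: str
    setup: str
    block: int
    trial_type: str
    trial_index: int
    start_angle: float
    target_location: tuple[float, float]
    probe_rotation: Optional[float] = None
    final_location: Optional[tuple[float, float]] = None

    def validate(self, arena: ArenaConfig) -> "TrialMeta":
        label = self.label()
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(f"{label}: unknown trial_type {self.trial_type!r}")
        is_probe = self.trial_type == "probe"
        if is_probe and self.probe_rotation is None:
            raise ValidationError(f"{label}: probe trial missing probe_rotation")
        if not is_probe and self.probe_rotation is not None:
            raise ValidationError(
                f"{label}: probe_rotation given for non-probe trial")
        tx, ty = self.target_location
        d = float(np.hypot(tx - arena.center[0], ty - arena.center[1]))
        if d >= arena.radius:
            raise ValidationError(
                f"{label}: target {self.target_location} outside arena")
        return self

    def label(self) -> str:
        return (f"participant={self.participant_id} setup={self.setup} "
                f"block={self.block} {self.trial_type} trial {self.trial_index}")


#: Stable column order for metric tables.
META_COLUMNS = [
    "participant_id", "group", "setup", "block", "trial_type", "trial_index",
    "start_angle", "probe_rotation", "target_x", "target_y",
    "final_x", "final_y",
]
METRIC_VALUE_COLUMNS = [
    "memory_score", "latency", "path_length", "path_error", "surface_coverage",
    "avg_distance_to_final", "idphi", "trajectory_distance",
]
METRIC_COLUMNS = META_COLUMNS + METRIC_VALUE_COLUMNS


@dataclass
class MetricRecord:
    """One trial's computed metrics in tidy-row form.

    Metrics undefined for a trial type (e.g. ``trajectory_distance`` on a
    learning trial) are ``None`` and serialize to empty cells, never zero.
    """

    participant_id: str
    group: str
    setup: str
    block: int
    trial_type: str
    trial_index: int
    start_angle: float
    probe_rotation: Optional[float]
    target_x: float
    target_y: float
    final_x: float
    final_y: float
    memory_score: Optional[float] = None
    latency: Optional[float] = None
    path_length: Optional[float] = None
    path_error: Optional[float] = None
    surface_coverage: Optional[float] = None
    avg_distance_to_final: Optional[float] = None
    idphi: Optional[float] = None
    trajectory_distance: Optional[float] = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
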