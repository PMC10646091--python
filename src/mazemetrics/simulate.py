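"""Synthetic water-maze navigators.

Generates complete synthetic experiments — block designs, trials, and agent
trajectories — with the geometry and trial structure of the virtual
water-maze task: a 3.8 m circular arena, six blocks of three learning plus
four probe trials, fixed per-block start locations on the six radial axes,
targets on quadrant center axes at a center distance uniform in
[0.2, 0.8] x radius, and probe starts rotated about the center by 0, 90, 180
or 270 degrees. Agents translate at 1.4 m/s and are sampled at 60 Hz
(stationary) or 90 Hz (mobile).

Three navigation strategies are modeled:

* ``direct`` — scan in place for a few seconds (yaw sweeping at the task's
  50 deg/s rotation speed), then walk toward a noisy estimate of the
  remembered target with per-step heading noise;
* ``random_search`` — correlated random walk with specular reflection at the
  arena wall, ending at the capture radius of the target (learning) or at
  the time limit (probe);
* ``path_replication`` — egocentric replay of the block's learning-trial
  motor sequence from the new start, without compensating for the probe
  rotation (the replayed displacement sequence rotates with the start).

Consecutive trials use independent RNG substreams, mirroring the task's
disorientation procedure that prevents carry-over between trials.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .io import write_session
from .types import ArenaConfig, TrialMeta, TrialTrajectory

__all__ = [
    "BlockDesign",
    "ExperimentDesign",
    "AgentSpec",
    "generate_design",
    "start_location",
    "simulate_trial",
    "simulate_block",
    "simulate_cohort",
    "DEFAULT_GROUP_EFFECTS",
]

START_ANGLES = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)
PROBE_ROTATIONS = (0.0, 90.0, 180.0, 270.0)
RELATIVE_TARGET_ANGLES = (-135.0, -45.0, 45.0, 135.0)
N_LEARNING = 3
N_PROBE = 4


@dataclass(frozen=True)
class BlockDesign:
    """Spatial parameters of one experimental block."""

    start_angle: float  # degrees, one of START_ANGLES
    target_location: tuple[float, float]
    probe_rotations: tuple[float, ...]  # permutation of PROBE_ROTATIONS


@dataclass(frozen=True)
class ExperimentDesign:
    """Six blocks of 3 learning + 4 probe trials."""

    blocks: tuple[BlockDesign, ...]

    def __post_init__(self) -> None:
        if len(self.blocks) != 6:
            raise ValueError("an experiment has exactly 6 blocks")


@dataclass(frozen=True)
class AgentSpec:
    """Parameters of one synthetic navigator.

    ``goal_noise_sigma`` is the s.d. (m) of the Gaussian error on the
    remembered target location; ``heading_noise_sigma`` the per-step heading
    perturbation (rad). ``scan_duration``/``scan_rate`` control the initial
    in-place scanning of the surrounding landmarks. Speed (1.4 m/s), capture
    radius (0.8 m), scan rate (50 deg/s) and sampling rates (60/90 Hz)
    default to the task's values.
    """

    strategy: str = "direct"
    goal_noise_sigma: float = 0.5
    heading_noise_sigma: float = 0.02
    scan_duration: float = 2.0
    scan_rate: float = math.radians(50.0)
    speed: float = 1.4
    capture_radius: float = 0.8
    sampling_rate: float = 60.0
    max_duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("direct", "random_search", "path_replication"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not self.speed > 0:
            raise ValueError("speed must be positive")
        if not self.capture_radius > 0:
            raise ValueError("capture_radius must be positive")


def generate_design(arena: ArenaConfig, seed: int) -> ExperimentDesign:
    """Reproducible 6-block design with the task's spatial constraints.

    Start locations sit on the arena boundary at the six radial axes (in a
    seeded random block order); each block's target lies on a quadrant center
    axis at +-45 or +-135 degrees relative to the start, with center distance
    uniform in [0.2, 0.8] x radius; probe rotations are a per-block
    permutation of (0, 90, 180, 270) degrees.
    """
    rng = np.random.default_rng(seed)
    cx, cy = arena.center
    blocks = []
    for start_angle in rng.permutation(START_ANGLES):
        rel = rng.choice(RELATIVE_TARGET_ANGLES)
        dist = arena.radius * rng.uniform(0.2, 0.8)
        ang = math.radians(start_angle + rel)
        target = (cx + dist * math.cos(ang), cy + dist * math.sin(ang))
        rotations = tuple(float(r) for r in rng.permutation(PROBE_ROTATIONS))
        blocks.append(BlockDesign(float(start_angle), target, rotations))
    return ExperimentDesign(tuple(blocks))


def start_location(block: BlockDesign, arena: ArenaConfig,
                   probe_rotation: float = 0.0) -> np.ndarray:
    """Start position on the boundary, rotated about the center for probes."""
    ang = math.radians(block.start_angle + probe_rotation)
    return arena.center_array + arena.radius * np.array(
        [math.cos(ang), math.sin(ang)])


def _clip_inside(pos: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    rel = pos - arena.center_array
    r = float(np.linalg.norm(rel))
    if r > arena.radius:
        pos = arena.center_array + rel * (arena.radius / r)
    return pos


def _scan_phase(pos, yaw0, agent, rng):
    """In-place scanning: yaw sweeps at scan_rate, alternating each second."""
    dt = 1.0 / agent.sampling_rate
    n = int(round(agent.scan_duration * agent.sampling_rate))
    positions, yaws = [], []
    yaw = yaw0
    direction = 1.0 if rng.random() < 0.5 else -1.0
    flip = max(int(agent.sampling_rate), 1)
    for i in range(n):
        if i > 0 and i % flip == 0:
            direction = -direction
        yaw += direction * agent.scan_rate * dt
        positions.append(pos.copy())
        yaws.append(yaw)
    return positions, yaws


def _walk_to_goal(pos, goal, agent, arena, rng, *, stop_radius, snap_to_goal,
                  t_used):
    """Step toward the goal at constant speed with per-step heading noise."""
    dt = 1.0 / agent.sampling_rate
    step = agent.speed * dt
    positions, yaws = [], []
    max_steps = max(int((agent.max_duration - t_used) * agent.sampling_rate), 1)
    for _ in range(max_steps):
        to_goal = goal - pos
        d = float(np.linalg.norm(to_goal))
        if snap_to_goal and d <= step:
            positions.append(goal.copy())
            yaws.append(math.atan2(to_goal[1], to_goal[0]) if d > 0 else 0.0)
            break
        heading = math.atan2(to_goal[1], to_goal[0])
        heading += rng.normal(0.0, agent.heading_noise_sigma)
        pos = _clip_inside(
            pos + step * np.array([math.cos(heading), math.sin(heading)]), arena)
        positions.append(pos.copy())
        yaws.append(heading)
        if not snap_to_goal and float(np.linalg.norm(goal - pos)) <= stop_radius:
            break
    return positions, yaws


def _random_search(pos, target, agent, arena, rng, *, stop_at_target, t_used):
    """Correlated random walk with specular reflection at the wall."""
    dt = 1.0 / agent.sampling_rate
    step = agent.speed * dt
    turn_sigma = max(agent.heading_noise_sigma, 0.15)
    # start heading: inward
    rel = pos - arena.center_array
    heading = math.atan2(-rel[1], -rel[0])
    positions, yaws = [], []
    max_steps = max(int((agent.max_duration - t_used) * agent.sampling_rate), 1)
    for _ in range(max_steps):
        heading += rng.normal(0.0, turn_sigma)
        v = np.array([math.cos(heading), math.sin(heading)])
        nxt = pos + step * v
        rel = nxt - arena.center_array
        if float(np.linalg.norm(rel)) > arena.radius:
            n_hat = (pos - arena.center_array)
            nrm = float(np.linalg.norm(n_hat))
            n_hat = n_hat / nrm if nrm > 0 else np.array([1.0, 0.0])
            v = v - 2.0 * float(v @ n_hat) * n_hat
            heading = math.atan2(v[1], v[0])
            nxt = _clip_inside(pos + step * v, arena)
        pos = nxt
        positions.append(pos.copy())
        yaws.append(heading)
        if stop_at_target and float(np.linalg.norm(pos - target)) <= agent.capture_radius:
            break
    return positions, yaws


def _replay(learned: TrialTrajectory, start: np.ndarray, rotation: float,
            agent, arena, rng):
    """Egocentric replay: learned displacements rotated with the start frame."""
    disp = np.diff(learned.positions, axis=0)
    ang = math.radians(rotation)
    c, s = math.cos(ang), math.sin(ang)
    rot = np.array([[c, -s], [s, c]])
    disp = disp @ rot.T
    if agent.heading_noise_sigma > 0:
        jitter = rng.normal(0.0, agent.heading_noise_sigma, len(disp))
        cj, sj = np.cos(jitter), np.sin(jitter)
        disp = np.column_stack((cj * disp[:, 0] - sj * disp[:, 1],
                                sj * disp[:, 0] + cj * disp[:, 1]))
    positions = [start.copy()]
    for d in disp:
        positions.append(_clip_inside(positions[-1] + d, arena))
    yaws = list(np.unwrap(learned.yaw) + ang)
    return positions[1:], yaws[1:]


def simulate_trial(block: BlockDesign, trial_type: str,
                   probe_rotation: Optional[float], agent: AgentSpec,
                   arena: ArenaConfig, *,
                   learned: Optional[TrialTrajectory] = None,
                   participant_id: str = "agent", group: str = "control",
                   setup: str = "stationary", blk_index: int = 1,
                   trial_index: int = 1,
                   rng: Optional[np.random.Generator] = None,
                   ) -> tuple[TrialMeta, TrialTrajectory]:
    """Simulate one trial of one agent; deterministic given the RNG state.

    ``learned`` must be the block's last simulated learning trajectory when
    the agent's strategy is ``path_replication`` on a probe trial.
    """
    if rng is None:
        rng = np.random.default_rng(agent.seed)
    is_probe = trial_type == "probe"
    rotation = float(probe_rotation) if is_probe else 0.0
    pos = start_location(block, arena, rotation)
    target = np.asarray(block.target_location, dtype=float)
    rel = pos - arena.center_array
    yaw0 = math.atan2(-rel[1], -rel[0])  # facing the arena center

    positions = [pos.copy()]
    yaws = [yaw0]
    dt = 1.0 / agent.sampling_rate

    strategy = agent.strategy
    if strategy == "path_replication" and is_probe:
        if learned is None:
            raise ValueError(
                "path replication requires a learning trajectory simulated "
                "earlier in the block")
        p, y = _replay(learned, pos, rotation, agent, arena, rng)
        positions += p
        yaws += y
    else:
        if strategy in ("direct", "path_replication"):
            # replication agents behave like direct agents on learning trials
            if agent.scan_duration > 0:
                p, y = _scan_phase(pos, yaw0, agent, rng)
                positions += p
                yaws += y
            t_used = len(positions) * dt
            if is_probe:
                goal = target + rng.normal(0.0, agent.goal_noise_sigma, 2)
                goal = _clip_inside(goal, ArenaConfig(
                    center=arena.center, radius=arena.radius * 0.99))
                p, y = _walk_to_goal(positions[-1], goal, agent, arena, rng,
                                     stop_radius=0.0, snap_to_goal=True,
                                     t_used=t_used)
            else:
                p, y = _walk_to_goal(positions[-1], target, agent, arena, rng,
                                     stop_radius=agent.capture_radius,
                                     snap_to_goal=False, t_used=t_used)
            positions += p
            yaws += y
        else:  # random_search
            p, y = _random_search(pos, target, agent, arena, rng,
                                  stop_at_target=not is_probe, t_used=0.0)
            positions += p
            yaws += y

    if len(positions) < 2:  # degenerate (e.g. start already at goal)
        positions.append(positions[-1].copy())
        yaws.append(yaws[-1])
    n = len(positions)
    traj = TrialTrajectory(
        timestamps=np.arange(n) * dt,
        positions=np.asarray(positions),
        yaw=np.asarray(yaws),
        sampling_rate=agent.sampling_rate,
    ).validate(arena, wall_tol=1e-9, label="simulated trial")
    meta = TrialMeta(
        participant_id=participant_id, group=group, setup=setup,
        block=blk_index, trial_type=trial_type, trial_index=trial_index,
        start_angle=block.start_angle,
        target_location=tuple(block.target_location),
        probe_rotation=rotation if is_probe else None,
        final_location=tuple(traj.final_location),
    ).validate(arena)
    return meta, traj


def simulate_block(block: BlockDesign, agent: AgentSpec, arena: ArenaConfig,
                   *, blk_index: int = 1, rng: Optional[np.random.Generator] = None,
                   **meta_kw) -> list[tuple[TrialMeta, TrialTrajectory]]:
    """Simulate 3 learning + 4 probe trials with fresh substreams per trial."""
    if rng is None:
        rng = np.random.default_rng(agent.seed)
    trials = []
    last_learning = None
    for i in range(N_LEARNING):
        meta, traj = simulate_trial(
            block, "learning", None, agent, arena, blk_index=blk_index,
            trial_index=i + 1, rng=np.random.default_rng(rng.integers(2**31)),
            **meta_kw)
        last_learning = traj
        trials.append((meta, traj))
    for i, rot in enumerate(block.probe_rotations):
        meta, traj = simulate_trial(
            block, "probe", rot, agent, arena, learned=last_learning,
            blk_index=blk_index, trial_index=N_LEARNING + i + 1,
            rng=np.random.default_rng(rng.integers(2**31)), **meta_kw)
        trials.append((meta, traj))
    return trials


#: Group x setup agent adjustments emulating the study's qualitative pattern:
#: the patient group remembers targets less precisely in the stationary setup
#: and both groups improve with full-body (mobile) sensory input.
DEFAULT_GROUP_EFFECTS: dict[tuple[str, str], dict] = {
    ("MTLR", "stationary"): {"goal_noise_sigma": 1.2, "scan_duration": 1.0},
    ("MTLR", "mobile"): {"goal_noise_sigma": 0.5, "scan_duration": 1.5},
    ("control", "stationary"): {"goal_noise_sigma": 0.6, "scan_duration": 2.0},
    ("control", "mobile"): {"goal_noise_sigma": 0.3, "scan_duration": 2.5},
}

_SETUP_RATES = {"stationary": 60.0, "mobile": 90.0}


def simulate_cohort(n_per_group: tuple[int, int] = (10, 20),
                    group_effects: Optional[Mapping] = None,
                    seed: int = 0, out_dir: str | Path = "cohort",
                    arena: Optional[ArenaConfig] = None,
                    base_agent: Optional[AgentSpec] = None) -> dict:
    """Simulate and write a full 2-group x 2-setup synthetic experiment.

    ``n_per_group = (n_MTLR, n_control)`` agents each complete both setups
    (stationary at 60 Hz, mobile at 90 Hz), 6 blocks x (3 learning + 4 probe)
    trials per setup, with counterbalanced setup order. ``group_effects``
    maps ``(group, setup)`` to AgentSpec field overrides
    (:data:`DEFAULT_GROUP_EFFECTS` by default). Output: per participant-setup
    trajectory and metadata CSVs, a participants table with covariates, and a
    run manifest; byte-identical across runs with the same seed.
    """
    arena = arena or ArenaConfig()
    base_agent = base_agent or AgentSpec()
    effects = DEFAULT_GROUP_EFFECTS if group_effects is None else group_effects
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = generate_design(arena, seed)

    participants = []
    files = {"trajectories": [], "meta": []}
    pidx = 0
    for group, n in zip(("MTLR", "control"), n_per_group):
        for k in range(n):
            pid = f"{'p' if group == 'MTLR' else 'c'}{k + 1:02d}"
            cov_rng = np.random.default_rng(
                np.random.SeedSequence([seed, pidx, 999]))
            session_order = ("stationary-first" if pidx % 2 == 0
                            else "mobile-first")
            participants.append({
                "participant": pid, "group": group,
                "session_order": session_order,
                "sex": "female" if cov_rng.random() < 0.6 else "male",
                "age": int(cov_rng.integers(22, 62)),
                "education_years": int(cov_rng.integers(12, 21)),
            })
            for sidx, setup in enumerate(("stationary", "mobile")):
                overrides = dict(effects.get((group, setup), {}))
                agent = replace(base_agent, sampling_rate=_SETUP_RATES[setup],
                                **overrides)
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, pidx, sidx]))
                block_order = rng.permutation(6)
                session = []
                for bpos, b in enumerate(block_order):
                    session += simulate_block(
                        design.blocks[b], agent, arena,
                        blk_index=bpos + 1, rng=rng, participant_id=pid,
                        group=group, setup=setup)
                tf = out_dir / f"{pid}_{setup}_trajectory.csv"
                mf = out_dir / f"{pid}_{setup}_meta.csv"
                write_session(session, tf, mf)
                files["trajectories"].append(str(tf))
                files["meta"].append(str(mf))
            pidx += 1

    import pandas as pd
    pd.DataFrame(participants).to_csv(out_dir / "participants.csv", index=False)
    arena.to_yaml(out_dir / "arena.yaml")
    manifest = {
        "seed": seed, "n_per_group": list(n_per_group),
        "group_effects": {f"{g}/{s}": v for (g, s), v in effects.items()},
        "arena": {"center": list(arena.center), "radius": arena.radius},
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
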