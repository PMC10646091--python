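import numpy as np
import pytest

from mazemetrics import ArenaConfig, TrialMeta, TrialTrajectory


@pytest.fixture
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trajectory(positions, sampling_rate=60.0, yaw=None, t0=0.0):
    """Build a TrialTrajectory from a position polyline at a fixed rate."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if yaw is None:
        yaw = np.zeros(n)
    t = t0 + np.arange(n) / sampling_rate
    return TrialTrajectory(t, positions, np.asarray(yaw, dtype=float),
                           sampling_rate)


def make_meta(trial_type="probe", target=(1.0, 1.0), final=None, **kw):
    defaults = dict(participant_id="p01", group="control", setup="stationary",
                    block=1, trial_index=1, start_angle=0.0,
                    probe_rotation=0.0 if trial_type == "probe" else None)
    defaults.update(kw)
    return TrialMeta(trial_type=trial_type, target_location=tuple(target),
                     final_location=final, **defaults)
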