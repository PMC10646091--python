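"""Orientation preprocessing: quaternion -> yaw, unwrapping, low-pass filtering.

Head orientation is recorded as unit quaternions; all downstream metrics use
only the heading about the vertical axis (yaw). The yaw channel is unwrapped
and low-pass filtered (zero-phase Butterworth, 6 Hz by default) so that the
angular-velocity statistic reflects head movements at behaviorally relevant
time scales rather than tracker jitter.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

__all__ = ["quaternion_to_yaw", "unwrap_angles", "lowpass_yaw", "preprocess_yaw"]

_CONVENTIONS = ("z_up", "unity_y_up")


def quaternion_to_yaw(q, axis_convention: str = "z_up") -> np.ndarray:
    """Extract the heading angle about the vertical axis from unit quaternions.

    Parameters
    ----------
    q : array-like, shape (4,) or (n, 4)
        Quaternion components ordered ``(w, x, y, z)``. Normalized internally;
        a zero-norm quaternion raises ``ValueError``.
    axis_convention : {"z_up", "unity_y_up"}
        ``z_up``: right-handed frame with z vertical;
        ``yaw = atan2(2(wz + xy), 1 - 2(y^2 + z^2))``.
        ``unity_y_up``: Unity's left-handed y-up frame, where positive yaw is
        clockwise seen from above; the sign is flipped so the returned yaw is
        counterclockwise-positive.

    Returns
    -------
    yaw : ndarray
        Radians in ``(-pi, pi]``; scalar input gives a 0-d result.
    """
    if axis_convention not in _CONVENTIONS:
        raise ValueError(f"axis_convention must be one of {_CONVENTIONS}")
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[-1] != 4:
        raise ValueError("quaternions must have 4 components (w, x, y, z)")
    norm = np.linalg.norm(q, axis=-1)
    if np.any(norm < 1e-12):
        raise ValueError("zero-norm quaternion cannot be normalized")
    w, x, y, z = (q / norm[:, None]).T
    if axis_convention == "z_up":
        yaw = np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    else:
        # rotation about the vertical y axis; negate for CCW-positive output
        yaw = -np.arctan2(2.0 * (w * y + x * z), 1.0 - 2.0 * (y * y + z * z))
    # map -pi (atan2 edge) into (-pi, pi]
    yaw = np.where(yaw <= -np.pi, yaw + 2.0 * np.pi, yaw)
    return yaw[0] if scalar else yaw


def unwrap_angles(yaw) -> np.ndarray:
    """Unwrap a yaw sequence so consecutive differences lie in ``(-pi, pi]``.

    The first element is unchanged and the output equals the input modulo 2*pi
    elementwise.
    """
    yaw = np.asarray(yaw, dtype=float)
    if yaw.size == 0:
        raise ValueError("need at least one sample")
    return np.unwrap(yaw)


def lowpass_yaw(yaw, sampling_rate: float, cutoff: float = 6.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of an unwrapped yaw channel.

    Applied forward-backward (``filtfilt``) with anti-symmetric (odd)
    reflective edge padding — which preserves linear yaw trends — so the
    filter adds no phase delay and the idPhi window is not shifted. If the
    sampling rate does not exceed twice the cutoff, or the sequence is shorter
    than the filter warm-up length, the signal is returned unfiltered with a
    logged warning.
    """
    yaw = np.asarray(yaw, dtype=float)
    if sampling_rate <= 2.0 * cutoff:
        logger.warning(
            "sampling rate %.3g Hz <= 2 x cutoff %.3g Hz; skipping low-pass",
            sampling_rate, cutoff)
        return yaw.copy()
    b, a = _signal.butter(4, cutoff, btype="low", fs=sampling_rate)
    padlen = 3 * (max(len(b), len(a)) - 1)
    if len(yaw) <= padlen:
        logger.warning(
            "sequence of %d samples shorter than filter warm-up (%d); "
            "returning unfiltered signal", len(yaw), padlen)
        return yaw.copy()
    return _signal.filtfilt(b, a, yaw, padtype="odd", padlen=padlen)


def preprocess_yaw(yaw, sampling_rate: float, cutoff: float = 6.0) -> np.ndarray:
    """Standard yaw pipeline: unwrap, then zero-phase low-pass."""
    return lowpass_yaw(unwrap_angles(yaw), sampling_rate, cutoff)
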