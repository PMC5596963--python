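"""Raw IMU signal conditioning: low-pass filtering and attitude correction.

Body-worn inertial sensors are never mounted perfectly aligned with the
world: each unit sits on the skin with some unknown pitch/roll tilt.  During
quiet standing the accelerometer reads pure gravity, so the mean specific
force over a short static trial gives the sensor's "down" direction.  The
minimal rotation carrying that measured gravity direction onto the global
vertical axis is then applied to every walking-trial acceleration sample,
expressing the data in a gravity-aligned frame (vertical, anteroposterior,
mediolateral).  Gravity carries no heading information, so yaw is left
untouched; anteroposterior/mediolateral labels follow the mounting
convention that the sensor's x axis points forward and y points laterally.

All six channels are low-pass filtered with a zero-phase 4th-order
Butterworth filter (10 Hz cutoff by default) before any further processing;
zero-phase application keeps gait-event timing intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

PLACEMENTS = ("back", "thigh", "shank", "foot")
TRIAL_TYPES = ("static", "walking")

#: sensor-frame axis labels before attitude correction
SENSOR_AXES = ("x", "y", "z")
#: global-frame axis labels after attitude correction
GLOBAL_AXES = ("ap", "ml", "vertical")

ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0


@dataclass
class SensorTrial:
    """One placement's 3-axis accelerometer + gyroscope recording.

    Accelerations are in g, angular velocities in degrees/s; rows are
    samples, columns are axes.  ``axes`` names the acceleration columns:
    sensor-frame ``(x, y, z)`` for raw data (z ≈ vertical when the mounting
    is untilted), ``(ap, ml, vertical)`` after attitude correction.
    """

    placement: str
    trial_type: str
    sample_rate: float
    accel: np.ndarray
    gyro: np.ndarray
    axes: tuple = SENSOR_AXES

    def __post_init__(self):
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        for name, arr in (("accel", self.accel), ("gyro", self.gyro)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"{name} must be a T x 3 array")
            if arr.shape[0] < 2:
                raise ValueError(f"{name} needs at least 2 samples")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.accel.shape[0] != self.gyro.shape[0]:
            raise ValueError("accel and gyro lengths differ")
        if np.abs(self.accel).max() > ACCEL_RANGE_G:
            raise ValueError(f"acceleration exceeds ±{ACCEL_RANGE_G} g range")
        if np.abs(self.gyro).max() > GYRO_RANGE_DPS:
            raise ValueError(f"angular velocity exceeds ±{GYRO_RANGE_DPS} °/s range")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class Attitude:
    """Rotation matrix mapping sensor frame -> gravity-aligned global frame."""

    placement: str
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = R


def lowpass_filter(trial: SensorTrial, cutoff_hz: float = 10.0, order: int = 4) -> SensorTrial:
    """Zero-phase Butterworth low-pass of all six channels.

    The filter is applied forward and backward (``filtfilt``) so waveform
    features keep their timing; each end is reflect-padded by one second
    (or the longest possible pad for very short trials) to suppress startup
    transients in the first gait cycle.
    """
    nyq = trial.sample_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyq} Hz")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=trial.sample_rate)
    pad = min(int(round(trial.sample_rate)), trial.n_samples - 1)

    def _run(x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((pad, pad), (0, 0)), mode="reflect")
        yp = signal.filtfilt(b, a, xp, axis=0, padlen=0)
        return yp[pad : pad + x.shape[0]] if pad else yp

    return replace(trial, accel=_run(trial.accel), gyro=_run(trial.gyro))


def estimate_attitude(static_trial: SensorTrial) -> Attitude:
    """Estimate mounting attitude from the gravity vector of a static trial.

    The mean accelerometer vector over the trial is taken as the gravity
    direction; the returned rotation is the minimal rotation (axis
    perpendicular to both) carrying it onto the global vertical (0, 0, 1).
    Heading about vertical is unobservable from gravity and left unchanged.
    The estimate is scale-invariant in the mean vector.
    """
    if static_trial.trial_type != "static":
        raise ValueError("attitude must be estimated from a static trial")
    if static_trial.duration_s < 1.0:
        raise ValueError("static trial shorter than 1 s")
    g_mean = static_trial.accel.mean(axis=0)
    norm = np.linalg.norm(g_mean)
    if not 0.5 <= norm <= 1.5:
        raise ValueError(
            f"static gravity magnitude {norm:.3f} g outside [0.5, 1.5] g: "
            "sensor not static or miscalibrated"
        )
    g_hat = g_mean / norm
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(g_hat, z)
    s = np.linalg.norm(axis)
    c = float(g_hat @ z)
    if s < 1e-12:
        if c > 0:  # already aligned
            R = np.eye(3)
        else:  # upside down: 180° about x by convention
            R = Rotation.from_rotvec([np.pi, 0.0, 0.0]).as_matrix()
    else:
        angle = np.arctan2(s, c)
        R = Rotation.from_rotvec(axis / s * angle).as_matrix()
    return Attitude(placement=static_trial.placement, rotation=R)


def apply_attitude(walking_trial: SensorTrial, att: Attitude) -> SensorTrial:
    """Rotate accelerations into the gravity-aligned global frame.

    Each acceleration row becomes ``R @ a``; rotation preserves per-sample
    norms.  Gyroscope channels are left in the sensor frame: gait-event
    detection uses the sensor-frame mediolateral angular velocity directly.
    """
    if att.placement != walking_trial.placement:
        raise ValueError(
            f"attitude for {att.placement!r} cannot correct a "
            f"{walking_trial.placement!r} trial"
        )
    accel = walking_trial.accel @ att.rotation.T
    return replace(walking_trial, accel=accel, axes=GLOBAL_AXES)
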