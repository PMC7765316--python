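"""Sensor calibration, root normalization and the dead-reckoning drift model.

A worn IMU reports acceleration in its own (sensor) frame together with a
sensor-to-global rotation. Classification-ready signals are obtained in three
steps, applied per frame and per sensor:

1. gravity removal and re-expression in a calibrated local frame,
       a_noG(t)   = R_imu(t) a_imu(t) - g
       a_local(t) = R_calib a_noG(t)
2. orientation calibration against the mounting ("virtual bone") rotation,
       R_local(t) = R_calib R_imu(t) R_bone
3. normalization against the body-root (pelvis) sensor,
       a_normalized(t) = R_root^{-1} (a_local(t) - a_root(t))
       R_normalized(t) = R_root^{-1} R_local(t)

Vectors are columns, rotations act by left multiplication, and R_root^{-1} is
taken as the transpose (orthonormality is validated on input).

Double integration of acceleration (dead reckoning) is included as a drift
diagnostic: a constant acceleration bias produces a position error that grows
quadratically with elapsed time, which is why the pipeline classifies
trajectory *shapes* rather than integrating raw signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GRAVITY, ROOT_VERTEX, VERTEX_NAMES, ImuRecording

__all__ = [
    "SensorFrame",
    "CalibrationState",
    "NormalizedFrame",
    "check_rotation",
    "calibrate_acceleration",
    "calibrate_orientation",
    "normalize_to_root",
    "calibration_from_pose",
    "dead_reckon",
    "reconstruct_trajectory",
    "normalized_feature_matrix",
    "save_calibration",
    "load_calibration",
]

_ORTHO_TOL = 1e-8


def check_rotation(R: np.ndarray, name: str = "rotation") -> np.ndarray:
    """Validate that R is a proper rotation (orthonormal, det +1)."""
    R = np.asarray(R, float)
    if R.shape != (3, 3):
        raise ValueError(f"{name} must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
        raise ValueError(f"{name} is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
        raise ValueError(f"{name} must have determinant +1")
    return R


@dataclass(frozen=True, eq=False)
class SensorFrame:
    """One raw IMU reading: sensor-frame acceleration and sensor-to-global
    orientation at time t."""

    a_imu: np.ndarray  # 3-vector, m/s^2
    R_imu: np.ndarray  # 3x3, sensor -> global
    t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_imu", np.asarray(self.a_imu, float))
        object.__setattr__(self, "R_imu", check_rotation(self.R_imu, "R_imu"))
        if self.a_imu.shape != (3,):
            raise ValueError("a_imu must be a 3-vector")


@dataclass(frozen=True, eq=False)
class CalibrationState:
    """Per-sensor calibration rotations and the gravity vector, obtained from
    a known initial calibration pose."""

    R_calib: np.ndarray = field(default_factory=lambda: np.eye(3))
    R_bone: np.ndarray = field(default_factory=lambda: np.eye(3))
    g: np.ndarray = field(default_factory=lambda: GRAVITY.copy())

    def __post_init__(self) -> None:
        object.__setattr__(self, "R_calib", check_rotation(self.R_calib, "R_calib"))
        object.__setattr__(self, "R_bone", check_rotation(self.R_bone, "R_bone"))
        g = np.asarray(self.g, float)
        if g.shape != (3,) or not np.all(np.isfinite(g)):
            raise ValueError("g must be a finite 3-vector")
        object.__setattr__(self, "g", g)


@dataclass(frozen=True, eq=False)
class NormalizedFrame:
    """Calibrated then root-normalized signal for one sensor at one frame."""

    a_local: np.ndarray
    R_local: np.ndarray
    a_normalized: np.ndarray | None = None
    R_normalized: np.ndarray | None = None


def calibrate_acceleration(frame: SensorFrame, calib: CalibrationState) -> np.ndarray:
    """Gravity-free local acceleration: R_calib (R_imu a_imu - g)."""
    a_nog = frame.R_imu @ frame.a_imu - calib.g
    return calib.R_calib @ a_nog


def calibrate_orientation(frame: SensorFrame, calib: CalibrationState) -> np.ndarray:
    """Calibrated local orientation: R_calib R_imu R_bone."""
    return calib.R_calib @ frame.R_imu @ calib.R_bone


def normalize_to_root(
    a_local: np.ndarray,
    R_local: np.ndarray,
    a_root: np.ndarray,
    R_root: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Express a sensor's calibrated signal relative to the body root:
    a_n = R_root^T (a_local - a_root), R_n = R_root^T R_local."""
    R_root = check_rotation(R_root, "R_root")
    R_local = check_rotation(R_local, "R_local")
    a_local = np.asarray(a_local, float)
    a_root = np.asarray(a_root, float)
    a_n = R_root.T @ (a_local - a_root)
    R_n = R_root.T @ R_local
    return a_n, R_n


def calibration_from_pose(R_imu_at_calibration: np.ndarray, g: np.ndarray = GRAVITY) -> CalibrationState:
    """Default synthetic calibration convention: R_calib is the inverse of the
    sensor orientation measured while the subject holds the calibration pose,
    and the virtual bone rotation is the identity."""
    R0 = check_rotation(R_imu_at_calibration, "R_imu_at_calibration")
    return CalibrationState(R_calib=R0.T, R_bone=np.eye(3), g=g)


def dead_reckon(
    a_series: np.ndarray,
    dt: float,
    x0: np.ndarray = (0.0, 0.0, 0.0),
    v0: np.ndarray = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Double-integrate acceleration with the semi-implicit update

        v_{t+dt} = v_t + dt a_{t+dt}
        x_{t+dt} = x_t + dt v_{t+dt}

    where ``a_series[k]`` is the acceleration at the *end* of step k. Returns
    len(a_series)+1 positions starting at x0. Any constant acceleration bias b
    integrates to an error of b dt^2 N(N+1)/2, i.e. quadratic drift in time.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a_series = np.atleast_2d(np.asarray(a_series, float))
    if a_series.size and not np.all(np.isfinite(a_series)):
        raise ValueError("accelerations must be finite")
    x = np.asarray(x0, float).copy()
    v = np.asarray(v0, float).copy()
    out = np.empty((a_series.shape[0] + 1, x.size))
    out[0] = x
    for k, a in enumerate(a_series):
        v = v + dt * a
        x = x + dt * v
        out[k + 1] = x
    return out


def reconstruct_trajectory(
    recording: ImuRecording,
    sensor: int,
    calib: CalibrationState,
    x0: np.ndarray,
    x1: np.ndarray | None = None,
) -> np.ndarray:
    """Dead-reckon one sensor of a recording back to positions.

    Gravity is removed via the calibration, then the calibrated global-frame
    acceleration is double-integrated from the true initial state (x0 and, if
    given, the first-step position x1 which pins the initial velocity
    consistently with the finite-difference acceleration).
    """
    dt = 1.0 / recording.sampling_rate
    n = recording.acc.shape[0]
    a = np.empty((n, 3))
    for k in range(n):
        frame = SensorFrame(a_imu=recording.acc[k, sensor], R_imu=recording.rot[k, sensor], t=k * dt)
        a[k] = calibrate_acceleration(frame, calib)
    x0 = np.asarray(x0, float)
    if x1 is None:
        v0 = np.zeros(3)
    else:
        # initial backward-difference velocity consistent with central-difference
        # acceleration: v_0 = (x_1 - x_0)/dt - dt a_0
        v0 = (np.asarray(x1, float) - x0) / dt - dt * a[0]
    # step k -> k+1 consumes the acceleration at frame k (the end of the
    # central-difference stencil it closes), recovering interior frames exactly
    return dead_reckon(a[:-1], dt, x0=x0, v0=v0)


def normalized_feature_matrix(recording: ImuRecording, calib_per_sensor: list[CalibrationState] | None = None) -> np.ndarray:
    """Flatten a six-sensor recording into the 60-dim per-frame feature vector
    used by the raw-signal classifiers: for each of the 5 non-root sensors,
    the root-normalized acceleration (3) and orientation (9), concatenated.
    """
    n_f, n_s = recording.acc.shape[:2]
    if n_s != len(VERTEX_NAMES):
        raise ValueError(f"expected {len(VERTEX_NAMES)} sensors, got {n_s}")
    if calib_per_sensor is None:
        calib_per_sensor = [CalibrationState() for _ in range(n_s)]
    dt = 1.0 / recording.sampling_rate
    non_root = [s for s in range(n_s) if s != ROOT_VERTEX]
    feats = np.empty((n_f, 12 * len(non_root)))
    for k in range(n_f):
        root_frame = SensorFrame(recording.acc[k, ROOT_VERTEX], recording.rot[k, ROOT_VERTEX], k * dt)
        a_root = calibrate_acceleration(root_frame, calib_per_sensor[ROOT_VERTEX])
        R_root = calibrate_orientation(root_frame, calib_per_sensor[ROOT_VERTEX])
        cols = []
        for s in non_root:
            frame = SensorFrame(recording.acc[k, s], recording.rot[k, s], k * dt)
            a_l = calibrate_acceleration(frame, calib_per_sensor[s])
            R_l = calibrate_orientation(frame, calib_per_sensor[s])
            a_n, R_n = normalize_to_root(a_l, R_l, a_root, R_root)
            cols.append(np.concatenate([a_n, R_n.ravel()]))
        feats[k] = np.concatenate(cols)
    return feats


def save_calibration(states: list[CalibrationState], path: str | Path) -> None:
    """Persist per-sensor calibration as CSV (sensor_id, 9 R_calib, 9 R_bone)."""
    rows = []
    for s, st in enumerate(states):
        rows.append(
            {"sensor_id": s}
            | {f"R_calib_{i}": v for i, v in enumerate(st.R_calib.ravel())}
            | {f"R_bone_{i}": v for i, v in enumerate(st.R_bone.ravel())}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_calibration(path: str | Path, g: np.ndarray = GRAVITY) -> list[CalibrationState]:
    df = pd.read_csv(path)
    states = []
    for _, row in df.sort_values("sensor_id").iterrows():
        Rc = np.array([row[f"R_calib_{i}"] for i in range(9)]).reshape(3, 3)
        Rb = np.array([row[f"R_bone_{i}"] for i in range(9)]).reshape(3, 3)
        states.append(CalibrationState(R_calib=Rc, R_bone=Rb, g=g))
    return states
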