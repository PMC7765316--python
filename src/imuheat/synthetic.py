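"""Synthetic motion cohorts emulating a six-sensor inertial motion-capture study.

This module generates labeled 3D trajectories for six tracked body points
(left/right wrist, left/right knee, head, lower back) performing 13 exercise
archetypes, plus physically consistent synthetic IMU streams derived from
those trajectories.  It stands in for an external pose-estimation stage: the
downstream pipeline (windowing, PCA flattening, heatmap rasterization,
classification) consumes per-vertex position time series and does not care how
they were produced.

Each activity is a parametric motion: a canonical planar shape (circle/ellipse,
linear oscillation, one-sided vertical dip, lateral zigzag, or an antiphase
composite) scaled per vertex by participation weights, rotated into a motion
plane, and offset from an anatomical rest posture.  Subjects differ by a
lognormal amplitude scale and a uniform phase offset, both drawn from a
generator seeded by (cohort seed, subject index) so that cohorts are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VERTEX_NAMES",
    "ACTIVITY_LABELS",
    "GRAVITY",
    "ActivitySpec",
    "CohortConfig",
    "MotionSequence",
    "ImuRecording",
    "SubjectParams",
    "default_activity_specs",
    "subject_params",
    "class_trajectory",
    "make_cohort",
    "imu_from_trajectory",
    "save_cohort",
    "load_cohort",
]

# Tracked body points, in fixed channel order. The lower back (pelvis) sensor
# is the body root used for normalization downstream.
VERTEX_NAMES = ("l_wrist", "r_wrist", "l_knee", "r_knee", "head", "pelvis")
ROOT_VERTEX = VERTEX_NAMES.index("pelvis")

# The 13 activity labels of the emulated protocol.
ACTIVITY_LABELS = (
    "arm_chest_crossings",
    "arm_circles",
    "arm_head_crossings",
    "arm_raises",
    "arm_stretches_up",
    "cross_stepping",
    "jumping_jacks",
    "leg_raises",
    "lunges",
    "side_stepping",
    "squats",
    "sumo_squats",
    "walking",
)

MOTION_FAMILIES = (
    "planar-circle",
    "linear-oscillation",
    "lateral-zigzag",
    "vertical-dip",
    "composite-antiphase",
)

# Global frame: right-handed, z-up, positions in meters.
GRAVITY = np.array([0.0, 0.0, -9.81])

# Rest posture (meters) of the six tracked points for a standing subject.
_REST = np.array(
    [
        [-0.60, 0.00, 1.00],  # l_wrist
        [0.60, 0.00, 1.00],  # r_wrist
        [-0.15, 0.00, 0.50],  # l_knee
        [0.15, 0.00, 0.50],  # r_knee
        [0.00, 0.00, 1.70],  # head
        [0.00, 0.00, 1.00],  # pelvis
    ]
)


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True, eq=False)
class ActivitySpec:
    """Parametric description of one activity class.

    ``aspect`` is the secondary-axis ratio of the canonical shape (minor/major
    for ellipses, tooth height/sweep for zigzags); it is what visually
    separates flat arcs from circles and shallow from steep stepping patterns
    after scale-normalizing rasterization.
    """

    name: str
    motion_family: str
    amplitude: float  # meters, primary-axis half-extent
    frequency: float  # Hz
    plane_orientation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )  # rotation applied to the canonical motion plane
    vertex_weights: np.ndarray = field(
        default_factory=lambda: np.ones(len(VERTEX_NAMES))
    )  # per-vertex participation in [0, 1]
    aspect: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "plane_orientation", np.asarray(self.plane_orientation, float))
        object.__setattr__(self, "vertex_weights", np.asarray(self.vertex_weights, float))
        if self.motion_family not in MOTION_FAMILIES:
            raise ValueError(f"unknown motion_family {self.motion_family!r}; expected one of {MOTION_FAMILIES}")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not self.frequency > 0:
            raise ValueError("frequency must be > 0")
        if self.plane_orientation.shape != (3, 3):
            raise ValueError("plane_orientation must be a 3x3 rotation matrix")
        w = self.vertex_weights
        if w.shape != (len(VERTEX_NAMES),) or np.any(w < 0) or np.any(w > 1):
            raise ValueError("vertex_weights must be 6 values in [0, 1]")


def default_activity_specs() -> tuple[ActivitySpec, ...]:
    """The canonical 13-class activity set (one spec per label).

    Weights follow which body parts carry each exercise; families and aspects
    encode the qualitative trajectory shape of the driving limb (full circles
    for arm circles, flat crossing arcs, straight raises, stepping zigzags,
    one-sided dips for squats, antiphase limb swings for jacks and walking).
    """
    specs = (
        ActivitySpec("arm_chest_crossings", "planar-circle", 0.30, 0.60,
                     _rot_z(90.0), [1, 1, 0, 0, 0, 0], aspect=0.25),
        ActivitySpec("arm_circles", "planar-circle", 0.30, 0.80,
                     np.eye(3), [1, 1, 0, 0, 0, 0], aspect=1.0),
        ActivitySpec("arm_head_crossings", "planar-circle", 0.30, 0.60,
                     _rot_z(90.0), [1, 1, 0, 0, 0.5, 0], aspect=0.25),
        ActivitySpec("arm_raises", "linear-oscillation", 0.35, 0.70,
                     np.eye(3), [1, 1, 0, 0, 0, 0]),
        ActivitySpec("arm_stretches_up", "linear-oscillation", 0.30, 0.70,
                     np.eye(3), [1, 1, 0, 0, 0.5, 0]),
        ActivitySpec("cross_stepping", "lateral-zigzag", 0.30, 0.80,
                     np.eye(3), [0.3, 0.3, 1, 1, 0.5, 0.5], aspect=0.8),
        ActivitySpec("jumping_jacks", "composite-antiphase", 0.35, 1.00,
                     np.eye(3), [1, 1, 1, 1, 0.5, 0.5], aspect=0.9),
        ActivitySpec("leg_raises", "linear-oscillation", 0.30, 0.60,
                     np.eye(3), [0, 0, 1, 1, 0, 0]),
        ActivitySpec("lunges", "planar-circle", 0.30, 0.50,
                     _rot_z(90.0), [0, 0, 1, 1, 0, 0.7], aspect=0.5),
        ActivitySpec("side_stepping", "lateral-zigzag", 0.30, 0.80,
                     np.eye(3), [0.3, 0.3, 1, 1, 0.5, 0.5], aspect=0.25),
        ActivitySpec("squats", "vertical-dip", 0.35, 0.50,
                     np.eye(3), [0, 0, 0.4, 0.4, 1, 1]),
        ActivitySpec("sumo_squats", "vertical-dip", 0.35, 0.50,
                     np.eye(3), [0.4, 0.4, 0.4, 0.4, 1, 1]),
        ActivitySpec("walking", "composite-antiphase", 0.25, 1.00,
                     np.eye(3), [0.5, 0.5, 1, 1, 0.3, 0.3], aspect=0.3),
    )
    assert tuple(s.name for s in specs) == ACTIVITY_LABELS
    return specs


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort; ``seed`` fully determines output."""

    n_subjects: int = 10
    classes: tuple[ActivitySpec, ...] = field(default_factory=default_activity_specs)
    sampling_rate: float = 60.0  # Hz
    duration_per_class: float = 20.0  # seconds of recording per subject and class
    subject_variation: float = 0.15  # lognormal sigma of amplitude scale
    noise_sd: float = 0.005  # meters, iid positional noise
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (leave-one-person-out needs at least 2)")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.duration_per_class > 0:
            raise ValueError("duration_per_class must be > 0")
        if self.noise_sd < 0 or self.subject_variation < 0:
            raise ValueError("noise_sd and subject_variation must be >= 0")
        if len(self.classes) == 0:
            raise ValueError("at least one activity class required")


@dataclass(frozen=True, eq=False)
class MotionSequence:
    """Per-frame 3D positions of the tracked vertices for one recording."""

    positions: np.ndarray  # frames x vertices x 3, meters
    subject_id: str
    label: str
    sampling_rate: float

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, float)
        object.__setattr__(self, "positions", p)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("positions must have shape (frames, vertices, 3)")
        if not np.all(np.isfinite(p)):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True, eq=False)
class ImuRecording:
    """Per-frame, per-sensor raw IMU signal (sensor-frame acceleration and
    sensor-to-global orientation), aligned with the vertex order."""

    acc: np.ndarray  # frames x sensors x 3, m/s^2, sensor frame
    rot: np.ndarray  # frames x sensors x 3 x 3, sensor -> global
    sampling_rate: float
    subject_id: str = ""
    label: str = ""


@dataclass(frozen=True)
class SubjectParams:
    amp_scale: float
    phase: float  # radians


def subject_params(seed: int, subject_index: int, variation: float) -> SubjectParams:
    """Per-subject amplitude scale (lognormal) and phase offset (uniform),
    drawn from a stream seeded by (seed, subject_index)."""
    rng = np.random.default_rng([seed, subject_index])
    amp = float(np.exp(rng.normal(0.0, variation)))
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    return SubjectParams(amp_scale=amp, phase=phase)


def _tri(u: np.ndarray) -> np.ndarray:
    """Triangle wave, period 1, range [-1, 1], tri(0) = 0 rising."""
    return (2.0 / np.pi) * np.arcsin(np.sin(2.0 * np.pi * np.asarray(u, float)))


def _canonical_shape(family: str, aspect: float, u: np.ndarray) -> np.ndarray:
    """Unit-amplitude canonical path in the x-z plane at cycle phase ``u``
    (one period per unit of u). Returns (len(u), 3)."""
    u = np.asarray(u, float)
    out = np.zeros(u.shape + (3,))
    th = 2.0 * np.pi * u
    if family in ("planar-circle", "composite-antiphase"):
        out[..., 0] = np.cos(th)
        out[..., 2] = aspect * np.sin(th)
    elif family == "linear-oscillation":
        out[..., 2] = np.sin(th)
    elif family == "vertical-dip":
        out[..., 2] = -0.5 * (1.0 - np.cos(th))
    elif family == "lateral-zigzag":
        out[..., 0] = _tri(u)
        out[..., 2] = aspect * np.abs(_tri(2.0 * u))
    else:  # pragma: no cover - guarded by ActivitySpec validation
        raise ValueError(f"unknown motion_family {family!r}")
    return out


# Per-vertex half-period offsets for the antiphase composite family:
# left limbs swing against right limbs, trunk in phase with the right side.
_ANTIPHASE_OFFSETS = np.array([0.5, 0.0, 0.0, 0.5, 0.0, 0.0])


def class_trajectory(
    spec: ActivitySpec,
    t: np.ndarray | float,
    params: SubjectParams | None = None,
) -> np.ndarray:
    """Evaluate the noiseless trajectory of all vertices at times ``t``.

    Returns an array of shape (len(t), n_vertices, 3). Deterministic given
    (spec, t, params); periodic in t with period 1/frequency.
    """
    if params is None:
        params = SubjectParams(amp_scale=1.0, phase=0.0)
    t = np.atleast_1d(np.asarray(t, float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    u = spec.frequency * t + params.phase / (2.0 * np.pi)  # cycle phase
    n_v = len(VERTEX_NAMES)
    pos = np.empty((t.size, n_v, 3))
    for v in range(n_v):
        uv = u
        if spec.motion_family in ("composite-antiphase", "lateral-zigzag"):
            uv = u + _ANTIPHASE_OFFSETS[v]
        shape = _canonical_shape(spec.motion_family, spec.aspect, uv)
        amp = spec.amplitude * spec.vertex_weights[v] * params.amp_scale
        pos[:, v, :] = _REST[v] + amp * shape @ spec.plane_orientation.T
    return pos


def make_cohort(config: CohortConfig) -> list[MotionSequence]:
    """Generate n_subjects x n_classes labeled recordings.

    Subjects are named ``s00`` .. ``s{N-1}``. Positional noise is iid Gaussian
    per frame, drawn from a per-sequence stream so that any subset of the
    cohort is reproducible from the config alone.
    """
    n_frames = int(round(config.duration_per_class * config.sampling_rate))
    t = np.arange(n_frames) / config.sampling_rate
    sequences: list[MotionSequence] = []
    for i in range(config.n_subjects):
        params = subject_params(config.seed, i, config.subject_variation)
        for c, spec in enumerate(config.classes):
            pos = class_trajectory(spec, t, params)
            if config.noise_sd > 0:
                rng = np.random.default_rng([config.seed, i, c, 0x5EED])
                pos = pos + rng.normal(0.0, config.noise_sd, size=pos.shape)
            sequences.append(
                MotionSequence(
                    positions=pos,
                    subject_id=f"s{i:02d}",
                    label=spec.name,
                    sampling_rate=config.sampling_rate,
                )
            )
    return sequences


def _velocity_tangent_frames(vel: np.ndarray) -> np.ndarray:
    """Orthonormal sensor frames whose first axis tracks the velocity
    direction; falls back to identity while the point is (nearly) still."""
    n = vel.shape[0]
    R = np.tile(np.eye(3), (n, 1, 1))
    speed = np.linalg.norm(vel, axis=1)
    up = np.array([0.0, 0.0, 1.0])
    last = np.eye(3)
    for k in range(n):
        if speed[k] > 1e-8:
            e1 = vel[k] / speed[k]
            a = np.cross(up, e1)
            if np.linalg.norm(a) < 1e-8:  # moving straight up/down
                a = np.cross(np.array([1.0, 0.0, 0.0]), e1)
            e2 = a / np.linalg.norm(a)
            e3 = np.cross(e1, e2)
            last = np.column_stack([e1, e2, e3])
        R[k] = last
    return R


def imu_from_trajectory(
    seq: MotionSequence,
    gravity: np.ndarray = GRAVITY,
    orientation_model: str = "identity",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImuRecording:
    """Synthesize the raw IMU stream a real sensor suite would have produced.

    Linear acceleration is the second central finite difference of position
    (endpoints copied from their neighbors). The sensor reports, in its own
    frame, the linear acceleration with gravity added back:

        a_imu = R_imu^T (a_lin + g)

    so that the standard gravity-removal calibration recovers a_lin exactly.
    A stationary sensor with identity orientation therefore reads g.
    """
    if seq.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate twice")
    if orientation_model not in ("identity", "velocity-tangent"):
        raise ValueError(f"unknown orientation_model {orientation_model!r}")
    g = np.asarray(gravity, float)
    dt = 1.0 / seq.sampling_rate
    p = seq.positions
    acc_lin = np.empty_like(p)
    acc_lin[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / dt**2
    acc_lin[0] = acc_lin[1]
    acc_lin[-1] = acc_lin[-2]

    n_f, n_v = p.shape[:2]
    rot = np.tile(np.eye(3), (n_f, n_v, 1, 1))
    if orientation_model == "velocity-tangent":
        vel = np.gradient(p, dt, axis=0)
        for v in range(n_v):
            rot[:, v] = _velocity_tangent_frames(vel[:, v])

    # a_imu = R^T (a_lin + g), per frame and sensor
    a_world = acc_lin + g
    acc = np.einsum("fvij,fvi->fvj", rot, a_world)
    if noise_sd > 0:
        rng = np.random.default_rng([seed, 0xACC])
        acc = acc + rng.normal(0.0, noise_sd, size=acc.shape)
    return ImuRecording(
        acc=acc, rot=rot, sampling_rate=seq.sampling_rate,
        subject_id=seq.subject_id, label=seq.label,
    )


def save_cohort(sequences: list[MotionSequence], out_dir: str | Path) -> None:
    """Write a cohort as one .npz of position tensors plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {f"seq_{k:04d}": s.positions for k, s in enumerate(sequences)}
    np.savez(out_dir / "cohort.npz", **arrays)
    manifest = pd.DataFrame(
        {
            "key": list(arrays),
            "subject_id": [s.subject_id for s in sequences],
            "label": [s.label for s in sequences],
            "frames": [s.n_frames for s in sequences],
            "sampling_rate": [s.sampling_rate for s in sequences],
        }
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)


def load_cohort(in_dir: str | Path) -> list[MotionSequence]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    with np.load(in_dir / "cohort.npz") as data:
        return [
            MotionSequence(
                positions=data[row.key],
                subject_id=str(row.subject_id),
                label=str(row.label),
                sampling_rate=float(row.sampling_rate),
            )
            for row in manifest.itertuples()
        ]
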