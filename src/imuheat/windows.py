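"""Fixed-length trajectory windows and PCA flattening from 3D to 2D.

Vertex trajectories are cut into equal-length windows (by default without
overlap) and each window is projected onto its top-2 principal axes. Body
motions are often subtle relative to any fixed image plane, so the projection
plane is fit per window and per vertex, maximizing the in-plane spread of that
body part's movement; a shared per-window basis across vertices is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import MotionSequence

__all__ = ["WindowConfig", "TrajectoryWindow", "ProjectedWindow", "segment", "pca_project"]


@dataclass(frozen=True)
class WindowConfig:
    """Windowing parameters.

    Defaults follow the classifier input contracts: 150 frames (2.5 s at
    60 Hz) per image sub-window, 300 frames (5 s) for raw-signal models;
    stride defaults to the window length (no overlap).
    """

    window_frames: int = 150
    stride_frames: int | None = None  # None -> window_frames (no overlap)
    vertices: tuple[int, ...] | None = None  # None -> all vertices, in order

    def __post_init__(self) -> None:
        if self.window_frames < 2:
            raise ValueError("window_frames must be >= 2")
        stride = self.window_frames if self.stride_frames is None else self.stride_frames
        if not 1 <= stride <= self.window_frames:
            raise ValueError("stride_frames must be in [1, window_frames]")
        object.__setattr__(self, "stride_frames", stride)


@dataclass(frozen=True, eq=False)
class TrajectoryWindow:
    """One fixed-length slice of a recording (all selected vertices)."""

    positions: np.ndarray  # window_frames x n_vertices x 3
    subject_id: str
    label: str
    start_frame: int


@dataclass(frozen=True, eq=False)
class ProjectedWindow:
    """A 3D vertex window flattened to its best-fit plane."""

    points_2d: np.ndarray  # frames x 2
    basis: np.ndarray  # 2 x 3, orthonormal rows (principal axes)
    explained_variance: np.ndarray  # 2 nonnegative, descending
    source: tuple = ()  # (subject_id, label, vertex, start_frame)
    is_constant: bool = False


def segment(seq: MotionSequence, cfg: WindowConfig) -> list[TrajectoryWindow]:
    """Slice a recording into windows; sequences shorter than one window
    yield an empty list."""
    n = seq.n_frames
    w, s = cfg.window_frames, cfg.stride_frames
    if n < w:
        return []
    verts = cfg.vertices if cfg.vertices is not None else tuple(range(seq.n_vertices))
    starts = range(0, n - w + 1, s)
    return [
        TrajectoryWindow(
            positions=seq.positions[a : a + w, list(verts), :],
            subject_id=seq.subject_id,
            label=seq.label,
            start_frame=a,
        )
        for a in starts
    ]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: flip each axis so its largest-magnitude
    loading is positive (ties resolved to the first coordinate by argmax)."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def pca_project(points_3d: np.ndarray, source: tuple = ()) -> ProjectedWindow:
    """Project a window of 3D points onto its top-2 principal axes.

    Points are centered and projected; explained variances are the top-2
    eigenvalues of the sample covariance (ddof=1). A window of identical
    points is returned as a flagged degenerate window with all-zero 2D points
    rather than raising.
    """
    X = np.asarray(points_3d, float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("points_3d must have shape (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    center = X.mean(axis=0)
    Xc = X - center
    if np.allclose(Xc, 0.0, atol=1e-12):
        return ProjectedWindow(
            points_2d=np.zeros((n, 2)),
            basis=np.eye(3)[:2],
            explained_variance=np.zeros(2),
            source=source,
            is_constant=True,
        )
    # SVD of the centered cloud: right singular vectors are principal axes,
    # singular values give covariance eigenvalues s^2/(n-1)
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    basis = _fix_signs(Vt[:2])
    evar = (svals[:2] ** 2) / (n - 1)
    return ProjectedWindow(
        points_2d=Xc @ basis.T,
        basis=basis,
        explained_variance=evar,
        source=source,
        is_constant=False,
    )
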