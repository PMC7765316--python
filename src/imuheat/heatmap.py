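"""Crossing-count heatmaps: rasterize 2D trajectory windows into images.

A projected trajectory window is mapped onto a fixed pixel grid and each
pixel counts how often the trajectory crossed it, adding frequency-of-visit
information to the purely spatial trace. Two counting modes exist:

* ``segments`` (default): every pixel whose unit square is touched by a
  straight segment between consecutive samples is incremented once per
  segment (a supercover line count, robust to sparse sampling);
* ``points``: each sample increments the pixel containing it, so the grid
  sum equals the number of samples.

The window's bounding box, expanded by a padding fraction, is mapped onto the
raster with a single isotropic scale (aspect-preserving, centered), so the
shape of the motion is preserved and the image is invariant to uniform
scaling of the input. Image samples for the classifier stack 4 consecutive
150-frame sub-windows x one channel per tracked vertex, giving the
4 x 6 x 64 x 64 tensor at the default raster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .windows import pca_project

__all__ = [
    "RasterConfig",
    "HeatmapSample",
    "rasterize",
    "normalize_heatmap",
    "build_image_sample",
    "samples_from_cohort",
    "export_heatmap_pngs",
]


@dataclass(frozen=True)
class RasterConfig:
    height: int = 64
    width: int = 64
    padding_fraction: float = 0.05
    line_mode: str = "segments"  # {"segments", "points"}
    normalize: str = "max"  # {"max", "none"}

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("raster must be at least 2x2")
        if self.padding_fraction < 0:
            raise ValueError("padding_fraction must be >= 0")
        if self.line_mode not in ("segments", "points"):
            raise ValueError("line_mode must be 'segments' or 'points'")
        if self.normalize not in ("max", "none"):
            raise ValueError("normalize must be 'max' or 'none'")


@dataclass(frozen=True, eq=False)
class HeatmapSample:
    """A classifier input: sub_windows x channels x H x W nonnegative tensor."""

    tensor: np.ndarray
    label: str
    subject_id: str = ""
    start_frame: int = 0
    augmented: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, float)
        object.__setattr__(self, "tensor", t)
        if t.ndim != 4:
            raise ValueError("tensor must be (sub_windows, channels, H, W)")
        if np.any(t < 0):
            raise ValueError("heatmap entries must be nonnegative")


def _to_raster(points: np.ndarray, height: int, width: int, padding: float) -> np.ndarray:
    """Map 2D points into continuous raster coordinates (x=column, y=row).

    The padded bounding square of the points is centered on the raster and
    scaled isotropically to the smaller raster dimension. Degenerate (single
    point) input maps to the raster center.
    """
    pts = np.asarray(points, float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    center = (lo + hi) / 2.0
    half = float(np.max(hi - lo)) / 2.0 * (1.0 + padding)
    if half <= 0.0:
        return np.tile([width / 2.0, height / 2.0], (pts.shape[0], 1))
    scale = min(height, width) / (2.0 * half)
    out = np.empty_like(pts)
    out[:, 0] = (pts[:, 0] - center[0]) * scale + width / 2.0
    out[:, 1] = (pts[:, 1] - center[1]) * scale + height / 2.0
    return out


def _point_counts(coords: np.ndarray, height: int, width: int) -> np.ndarray:
    """Half-open binning: pixel (r, c) covers [r, r+1) x [c, c+1); the maximum
    coordinate falls into the last pixel."""
    cols = np.clip(np.floor(coords[:, 0]).astype(int), 0, width - 1)
    rows = np.clip(np.floor(coords[:, 1]).astype(int), 0, height - 1)
    grid = np.zeros((height, width))
    np.add.at(grid, (rows, cols), 1.0)
    return grid


_EPS = 1e-12
_BORDER_TOL = 1e-9


def _exact_box_hit(x0: float, y0: float, x1: float, y1: float, c: int, r: int) -> bool:
    """Exact rational slab test: does segment (x0,y0)-(x1,y1) touch the
    closed unit square [c, c+1] x [r, r+1]?"""
    from fractions import Fraction as F

    lo, hi = F(0), F(1)
    for p0, p1, b in (
        (F(float(x0)), F(float(x1)), F(int(c))),
        (F(float(y0)), F(float(y1)), F(int(r))),
    ):
        d = p1 - p0
        if d == 0:
            if not (b <= p0 <= b + 1):
                return False
            continue
        t1, t2 = (b - p0) / d, (b + 1 - p0) / d
        if t1 > t2:
            t1, t2 = t2, t1
        lo, hi = max(lo, t1), min(hi, t2)
    return lo <= hi


def _segment_pixels(p: np.ndarray, q: np.ndarray, height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of every pixel whose closed unit square the segment
    p->q touches (supercover coverage, via a vectorized slab test)."""
    x0, y0 = p
    x1, y1 = q
    dx, dy = x1 - x0, y1 - y0
    if abs(dx) < _EPS and abs(dy) < _EPS:  # degenerate: a point
        c = min(max(int(np.floor(x0)), 0), width - 1)
        r = min(max(int(np.floor(y0)), 0), height - 1)
        return np.array([r]), np.array([c])
    cmin = min(max(int(np.floor(min(x0, x1))), 0), width - 1)
    cmax = min(max(int(np.floor(max(x0, x1))), 0), width - 1)
    rmin = min(max(int(np.floor(min(y0, y1))), 0), height - 1)
    rmax = min(max(int(np.floor(max(y0, y1))), 0), height - 1)
    cols = np.arange(cmin, cmax + 1, dtype=float)
    rows = np.arange(rmin, rmax + 1, dtype=float)
    C, R = np.meshgrid(cols, rows)

    def slab(lo, origin, d):
        if abs(d) < _EPS:
            inside = (origin >= lo - _EPS) & (origin <= lo + 1.0 + _EPS)
            tlo = np.where(inside, -np.inf, np.inf)
            thi = np.where(inside, np.inf, -np.inf)
        else:
            t1 = (lo - origin) / d
            t2 = (lo + 1.0 - origin) / d
            tlo, thi = np.minimum(t1, t2), np.maximum(t1, t2)
        return tlo, thi

    tlo_x, thi_x = slab(C, x0, dx)
    tlo_y, thi_y = slab(R, y0, dy)
    tmin = np.maximum(np.maximum(tlo_x, tlo_y), 0.0)
    tmax = np.minimum(np.minimum(thi_x, thi_y), 1.0)
    hit = tmin <= tmax - _BORDER_TOL
    border = ~hit & (tmin <= tmax + _BORDER_TOL)
    if np.any(border):
        # near corner grazes float slack is unreliable; decide exactly
        for i, j in zip(*np.nonzero(border)):
            hit[i, j] = _exact_box_hit(x0, y0, x1, y1, cmin + j, rmin + i)
    rr, cc = np.nonzero(hit)
    return rr + rmin, cc + cmin


def rasterize(points_2d: np.ndarray, cfg: RasterConfig) -> np.ndarray:
    """Crossing-count grid of a 2D trajectory window (integer-valued counts,
    before normalization)."""
    pts = np.asarray(points_2d, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points_2d must have shape (n >= 1, 2)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points_2d must be finite")
    coords = _to_raster(pts, cfg.height, cfg.width, cfg.padding_fraction)
    if cfg.line_mode == "points":
        return _point_counts(coords, cfg.height, cfg.width)
    grid = np.zeros((cfg.height, cfg.width))
    if coords.shape[0] == 1:
        return _point_counts(coords, cfg.height, cfg.width)
    for k in range(coords.shape[0] - 1):
        rr, cc = _segment_pixels(coords[k], coords[k + 1], cfg.height, cfg.width)
        grid[rr, cc] += 1.0
    return grid


def normalize_heatmap(grid: np.ndarray, cfg: RasterConfig) -> np.ndarray:
    """Scale counts into [0, 1] by the maximum entry; an all-zero grid (and
    ``normalize='none'``) passes through unchanged."""
    grid = np.asarray(grid, float)
    if np.any(grid < 0):
        raise ValueError("grid must be nonnegative")
    if cfg.normalize == "none":
        return grid
    m = grid.max()
    return grid if m == 0 else grid / m


def build_image_sample(
    positions: np.ndarray,
    cfg: RasterConfig,
    label: str = "",
    subject_id: str = "",
    start_frame: int = 0,
    n_sub: int = 4,
    sub_window: int = 150,
    shared_basis: bool = False,
) -> HeatmapSample:
    """Assemble one classifier input from a (frames, vertices, 3) segment.

    The segment is split into ``n_sub`` consecutive sub-windows; each
    sub-window of each vertex is PCA-projected and rasterized into its own
    channel. With ``shared_basis`` the projection plane of each sub-window is
    fit once on all vertices' centered points instead of per vertex.
    """
    P = np.asarray(positions, float)
    need = n_sub * sub_window
    if P.ndim != 3 or P.shape[0] < need:
        raise ValueError(
            f"segment must have at least n_sub*sub_window = {need} frames, got {P.shape[0]}"
        )
    n_vert = P.shape[1]
    tensor = np.zeros((n_sub, n_vert, cfg.height, cfg.width))
    for w in range(n_sub):
        chunk = P[w * sub_window : (w + 1) * sub_window]
        basis = None
        if shared_basis:
            stacked = np.concatenate([chunk[:, v] - chunk[:, v].mean(axis=0) for v in range(n_vert)])
            basis = pca_project(stacked).basis
        for v in range(n_vert):
            if basis is None:
                pts2d = pca_project(chunk[:, v]).points_2d
            else:
                pts2d = (chunk[:, v] - chunk[:, v].mean(axis=0)) @ basis.T
            grid = rasterize(pts2d, cfg)
            tensor[w, v] = normalize_heatmap(grid, cfg)
    return HeatmapSample(
        tensor=tensor, label=label, subject_id=subject_id, start_frame=start_frame
    )


def samples_from_cohort(
    sequences,
    cfg: RasterConfig,
    n_sub: int = 4,
    sub_window: int = 150,
    vertices: tuple[int, ...] | None = None,
    shared_basis: bool = False,
) -> list[HeatmapSample]:
    """Cut every recording into non-overlapping n_sub*sub_window segments and
    build one heatmap sample per segment. ``vertices`` restricts the tracked
    channels (single-sensor ablations)."""
    seg_len = n_sub * sub_window
    samples: list[HeatmapSample] = []
    for seq in sequences:
        P = seq.positions if vertices is None else seq.positions[:, list(vertices), :]
        for a in range(0, P.shape[0] - seg_len + 1, seg_len):
            samples.append(
                build_image_sample(
                    P[a : a + seg_len],
                    cfg,
                    label=seq.label,
                    subject_id=seq.subject_id,
                    start_frame=a,
                    n_sub=n_sub,
                    sub_window=sub_window,
                    shared_basis=shared_basis,
                )
            )
    return samples


def export_heatmap_pngs(sample: HeatmapSample, out_dir: str | Path, vertex_names=None) -> list[Path]:
    """Write each channel of each sub-window as an 8-bit grayscale PNG named
    ``{label}_{subject}_{start}_t{sub}_{vertex}.png`` for visual inspection."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    T, C = sample.tensor.shape[:2]
    names = vertex_names or [f"v{c}" for c in range(C)]
    paths = []
    for t in range(T):
        for c in range(C):
            img = sample.tensor[t, c]
            m = img.max()
            arr = np.zeros_like(img, dtype=np.uint8) if m == 0 else (img / m * 255).astype(np.uint8)
            p = out_dir / f"{sample.label}_{sample.subject_id}_{sample.start_frame}_t{t}_{names[c]}.png"
            Image.fromarray(arr).save(p)
            paths.append(p)
    return paths
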