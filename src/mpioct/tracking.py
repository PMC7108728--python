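"""Sub-voxel marker localisation and trajectory cleaning.

Per frame: relative thresholding, connected-component selection and a
centre-of-mass estimate give the marker position; per series the samples
are cropped to the robust field of view, outliers are removed (running
median + windowed RANSAC) and the trajectory is smoothed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom_sim import ImageSeries4D

__all__ = [
    "Trajectory4D",
    "TrackingParams",
    "threshold_segment",
    "select_marker_region",
    "center_of_mass",
    "track_series",
    "clean_trajectory",
]


@dataclass
class Trajectory4D:
    """Timestamped 3D marker positions with validity and FoV-entry marks."""

    timestamps: np.ndarray          # (T,) s, strictly increasing
    positions: np.ndarray           # (T, 3) mm
    valid: np.ndarray               # (T,) bool
    in_crop: np.ndarray | None = None   # valid and inside the cropped FoV
    m1_index: int | None = None     # first sample inside the cropped FoV
    m2_index: int | None = None     # last sample inside the cropped FoV
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.timestamps) == len(self.positions) == len(self.valid)):
            raise ValueError("timestamps, positions and valid must align")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.m1_index is not None and self.m2_index is not None:
            if not self.m1_index < self.m2_index:
                raise ValueError("m1_index must precede m2_index")
        if np.any(~np.isfinite(self.positions[self.valid])):
            raise ValueError("valid samples must have finite positions")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def t_m1(self) -> float:
        if self.m1_index is None:
            raise ValueError("m1 not set")
        return float(self.timestamps[self.m1_index])

    @property
    def t_m2(self) -> float:
        if self.m2_index is None:
            raise ValueError("m2 not set")
        return float(self.timestamps[self.m2_index])


@dataclass(frozen=True)
class TrackingParams:
    theta: float = 0.35                     # relative intensity threshold
    crop_x: tuple[float, float] = (8.0, 18.0)
    ransac_window: int = 21
    ransac_tol: float = 1.0                 # mm
    ransac_trials: int = 100
    smooth_window: int = 9
    median_window: int = 11
    hard_tol: float = 3.0                   # mm, extreme-outlier cutoff
    weighting: str = "excess"

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if not self.crop_x[0] < self.crop_x[1]:
            raise ValueError("crop_x must be (low, high) with low < high")


def threshold_segment(frame: np.ndarray, theta: float) -> np.ndarray:
    """Binary mask of voxels with intensity >= theta * frame maximum."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    m = frame.max()
    if m <= 0:
        warnings.warn("frame maximum is not positive; empty segmentation")
        return np.zeros_like(frame, dtype=bool)
    return frame >= theta * m


def select_marker_region(mask: np.ndarray, frame: np.ndarray
                         ) -> np.ndarray | None:
    """Connected component of the mask with the highest peak intensity.

    Components are labelled with full (26-)connectivity.  Ties on peak
    intensity are broken by larger component size, then by the lowest
    linear voxel index.  Returns a boolean region mask, or None if the
    mask is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    frame = np.asarray(frame)
    structure = np.ones((3,) * mask.ndim, dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return None
    idx = np.arange(1, n + 1)
    peaks = ndimage.maximum(frame, labels, idx)
    sizes = ndimage.sum_labels(mask, labels, idx)
    lin = np.arange(mask.size).reshape(mask.shape)
    first = ndimage.minimum(lin, labels, idx)
    order = sorted(range(n), key=lambda i: (-peaks[i], -sizes[i], first[i]))
    return labels == idx[order[0]]


def center_of_mass(region: np.ndarray, frame: np.ndarray,
                   voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                   weighting: str = "intensity",
                   baseline: float = 0.0) -> np.ndarray:
    """Weighted mean of voxel-centre world coordinates over a region.

    ``weighting="intensity"`` weights by the frame values;
    ``weighting="binary"`` weights every region voxel equally;
    ``weighting="excess"`` weights by the intensity above ``baseline``
    (the segmentation level), which removes the truncation bias of the
    hard region boundary and is the most accurate sub-voxel variant.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    if weighting == "intensity":
        w = np.asarray(frame, dtype=float)[region]
    elif weighting == "binary":
        w = np.ones(int(region.sum()))
    elif weighting == "excess":
        w = np.clip(np.asarray(frame, dtype=float)[region] - baseline,
                    0.0, None)
        if w.sum() <= 0:
            w = np.ones(int(region.sum()))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    idx = np.argwhere(region)
    coords = np.asarray(origin, float) + (idx + 0.5) * np.asarray(voxel_size,
                                                                  float)
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def track_series(series: ImageSeries4D,
                 params: TrackingParams | None = None) -> Trajectory4D:
    """Localise the marker in every frame of a series.

    Frames where segmentation or localisation fails become invalid
    samples.  ``m1``/``m2`` mark the first/last frame whose x position
    lies inside the cropped FoV; samples outside it are kept but flagged
    as not robust via ``in_crop``.
    """
    params = params or TrackingParams()
    n = len(series)
    positions = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            frame = series.frames[i]
            if frame.max() <= 0:
                continue
            mask = threshold_segment(frame, params.theta)
            region = select_marker_region(mask, frame)
            if region is None:
                continue
            positions[i] = center_of_mass(
                region, frame, series.voxel_size, series.origin,
                params.weighting, baseline=params.theta * frame.max())
            valid[i] = True
    lo, hi = params.crop_x
    in_crop = valid & (positions[:, 0] >= lo) & (positions[:, 0] <= hi)
    where = np.flatnonzero(in_crop)
    m1 = int(where[0]) if len(where) else None
    m2 = int(where[-1]) if len(where) else None
    return Trajectory4D(series.timestamps.copy(), positions, valid,
                        in_crop=in_crop, m1_index=m1, m2_index=m2,
                        meta={"theta": params.theta, "crop_x": params.crop_x})


def _ransac_line_inliers(t: np.ndarray, x: np.ndarray, tol: float,
                         trials: int, rng: np.random.Generator) -> np.ndarray:
    """Inlier mask of the best 2-point consensus line x(t)."""
    n = len(t)
    best_inl, best_cnt = None, -1
    for _ in range(trials):
        i, j = rng.choice(n, size=2, replace=False)
        if t[i] == t[j]:
            continue
        slope = (x[j] - x[i]) / (t[j] - t[i])
        res = np.abs(x - (x[i] + slope * (t - t[i])))
        inl = res <= tol
        cnt = int(inl.sum())
        if cnt > best_cnt:
            best_cnt, best_inl = cnt, inl
    if best_inl is None or best_inl.sum() < 2:
        return np.ones(n, dtype=bool)
    p = np.polyfit(t[best_inl], x[best_inl], 1)
    return np.abs(x - np.polyval(p, t)) <= tol


def _moving_average(a: np.ndarray, half: int) -> np.ndarray:
    """Centred moving average with a symmetrically shrinking edge window
    (exact on linear sequences sampled uniformly)."""
    n = len(a)
    out = np.empty_like(a, dtype=float)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = a[i - h:i + h + 1].mean()
    return out


def clean_trajectory(traj: Trajectory4D,
                     params: TrackingParams | None = None,
                     seed: int = 0) -> Trajectory4D:
    """Remove outliers and smooth a tracked trajectory.

    Three stages on the valid samples: (1) samples farther than
    ``hard_tol`` from a per-coordinate running median are invalidated;
    (2) inside sliding windows a RANSAC line fit of x versus time
    invalidates samples with residual above ``ransac_tol``; (3) the
    surviving samples are smoothed per coordinate with a centred moving
    average of ``smooth_window`` samples.  Timestamps are never changed
    and no samples are fabricated.
    """
    params = params or TrackingParams()
    if int(traj.valid.sum()) < 5:
        raise ValueError("need at least 5 valid samples")
    rng = np.random.default_rng(seed)
    valid = traj.valid.copy()
    pos = traj.positions.copy()

    # stage 1: extreme outliers vs per-coordinate running median
    vi = np.flatnonzero(valid)
    med = np.column_stack([
        ndimage.median_filter(pos[vi, a], size=params.median_window,
                              mode="nearest")
        for a in range(3)])
    dist = np.linalg.norm(pos[vi] - med, axis=1)
    valid[vi[dist > params.hard_tol]] = False

    # stage 2: windowed RANSAC on x(t)
    vi = np.flatnonzero(valid)
    if len(vi) >= 5:
        w = params.ransac_window
        step = max(w // 2, 1)
        bad = np.zeros(len(vi), dtype=bool)
        for s in range(0, len(vi), step):
            sl = slice(s, min(s + w, len(vi)))
            if sl.stop - sl.start < 5:
                continue
            t_w = traj.timestamps[vi[sl]]
            x_w = pos[vi[sl], 0]
            inl = _ransac_line_inliers(t_w, x_w, params.ransac_tol,
                                       params.ransac_trials, rng)
            bad[sl] |= ~inl
        valid[vi[bad]] = False

    # stage 3: centred moving-average smoothing of the valid samples
    vi = np.flatnonzero(valid)
    half = max(params.smooth_window // 2, 0)
    for a in range(3):
        pos[vi, a] = _moving_average(pos[vi, a], half)

    lo, hi = params.crop_x
    in_crop = valid & (pos[:, 0] >= lo) & (pos[:, 0] <= hi)
    where = np.flatnonzero(in_crop)
    m1 = int(where[0]) if len(where) else None
    m2 = int(where[-1]) if len(where) else None
    return Trajectory4D(traj.timestamps.copy(), pos, valid, in_crop=in_crop,
                        m1_index=m1, m2_index=m2,
                        meta={**traj.meta, "cleaned": True, "seed": seed})
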