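"""Evaluation statistics for trajectories and volume reconstructions.

Envelopes of boundary point clouds, projected-silhouette Dice overlap,
full-width-at-half-maximum stenosis length, and trajectory mean absolute
error / per-segment velocity-regression errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom_sim import MotionProfile, PointCloud4D
from .reconstruction import SyncInfo
from .tracking import Trajectory4D

__all__ = [
    "EnvelopeModel",
    "TrackingErrorReport",
    "envelope",
    "projected_shape",
    "dice",
    "dice_clouds",
    "stenosis_length",
    "trajectory_errors",
]


@dataclass
class EnvelopeModel:
    """Per-axial-bin envelope radius of a boundary point cloud."""

    x_centers: np.ndarray
    radius: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.x_centers = np.asarray(self.x_centers, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if len(self.x_centers) != len(self.radius):
            raise ValueError("x_centers and radius must align")
        if len(self.x_centers) > 1 and np.any(np.diff(self.x_centers) <= 0):
            raise ValueError("x_centers must be strictly increasing")
        if np.any(self.radius[np.isfinite(self.radius)] <= 0):
            raise ValueError("envelope radii must be positive")

    def radius_at(self, x) -> np.ndarray:
        return np.interp(x, self.x_centers, self.radius)


@dataclass
class TrackingErrorReport:
    """Trajectory accuracy summary: positional MAE/SD inside the tracked
    window plus per-segment velocity regression errors."""

    mae: float
    sd: float
    n_samples: int
    segments: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mae < 0 or self.sd < 0:
            raise ValueError("mae and sd must be >= 0")


def envelope(cloud: PointCloud4D, bin_width: float = 0.25, q: float = 0.9,
             x_range: tuple[float, float] | None = None) -> EnvelopeModel:
    """Per-x-bin robust upper-quantile radius of a point cloud.

    Empty bins are filled by linear interpolation between covered bins.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    x = cloud.x
    rad = cloud.radii
    lo, hi = x_range if x_range is not None else (x.min(), x.max())
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    if len(edges) < 3:
        raise ValueError("cloud spans fewer than 2 bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(centers) - 1)
    inside = (x >= lo) & (x <= hi)
    order = np.argsort(idx[inside], kind="stable")
    idx_s = idx[inside][order]
    rad_s = rad[inside][order]
    radius = np.full(len(centers), np.nan)
    starts = np.searchsorted(idx_s, np.arange(len(centers)))
    stops = np.searchsorted(idx_s, np.arange(len(centers)) + 1)
    for b in range(len(centers)):
        if stops[b] > starts[b]:
            radius[b] = np.quantile(rad_s[starts[b]:stops[b]], q)
    good = np.isfinite(radius)
    if good.sum() < 2:
        raise ValueError("cloud covers fewer than 2 bins")
    radius = np.interp(centers, centers[good], radius[good])
    return EnvelopeModel(centers, radius, bin_width)


def _mask_grid(x_range: tuple[float, float], y_half: float, raster: float):
    """Pixel-centre coordinates of the silhouette raster (columns along x,
    rows along the projected transverse axis, symmetric about zero)."""
    nx = int(round((x_range[1] - x_range[0]) / raster))
    ny = 2 * int(round(y_half / raster))
    xc = x_range[0] + (np.arange(nx) + 0.5) * raster
    yc = (np.arange(ny) - ny / 2 + 0.5) * raster
    return xc, yc


def projected_shape(obj: EnvelopeModel | PointCloud4D, angle_deg: float = 0.0,
                    raster: float = 0.05,
                    x_range: tuple[float, float] | None = None,
                    y_half: float = 1.6,
                    bin_width: float = 0.25, q: float = 0.98) -> np.ndarray:
    """Rasterised 2D silhouette of a rotated envelope or point cloud.

    The object is rotated about the x axis by ``angle_deg`` and
    orthographically projected onto the (x, y') plane; the filled region
    between the lower and upper boundary is rasterised at ``raster`` mm
    per pixel (rows = transverse axis, columns = x).  For an
    ``EnvelopeModel`` — rotationally symmetric by construction — the
    silhouette spans ``[-radius, +radius]`` at every angle.
    """
    if not 0.0 <= angle_deg < 360.0:
        raise ValueError("angle must be in [0, 360)")
    if isinstance(obj, EnvelopeModel):
        if x_range is None:
            x_range = (float(obj.x_centers[0] - obj.bin_width / 2),
                       float(obj.x_centers[-1] + obj.bin_width / 2))
        xc, yc = _mask_grid(x_range, y_half, raster)
        r = obj.radius_at(xc)
        upper, lower = r, -r
    else:
        cloud = obj
        if len(cloud) == 0:
            raise ValueError("empty cloud")
        a = np.deg2rad(angle_deg)
        yp = cloud.points[:, 1] * np.cos(a) + cloud.points[:, 2] * np.sin(a)
        if x_range is None:
            x_range = (float(cloud.x.min()), float(cloud.x.max()))
        xc, yc = _mask_grid(x_range, y_half, raster)
        edges = np.arange(x_range[0], x_range[1] + bin_width * 0.5, bin_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        idx = np.clip(np.digitize(cloud.x, edges) - 1, 0, len(centers) - 1)
        up = np.full(len(centers), np.nan)
        lo_b = np.full(len(centers), np.nan)
        for b in range(len(centers)):
            sel = idx == b
            if sel.any():
                up[b] = np.quantile(yp[sel], q)
                lo_b[b] = np.quantile(yp[sel], 1.0 - q)
        good = np.isfinite(up)
        if good.sum() < 2:
            raise ValueError("cloud covers fewer than 2 bins")
        upper = np.interp(xc, centers[good], up[good])
        lower = np.interp(xc, centers[good], lo_b[good])
    return (yc[:, None] >= lower[None, :]) & (yc[:, None] <= upper[None, :])


def dice(shapes_u: list[np.ndarray], shapes_v: list[np.ndarray]) -> float:
    """Mean over paired masks of ``2 |U ∩ V| / (|U| + |V|)``.

    Pairs where both masks are empty are counted as 0 and flagged with a
    warning.
    """
    if len(shapes_u) != len(shapes_v) or len(shapes_u) == 0:
        raise ValueError("need equal, non-zero numbers of masks")
    terms = []
    for u, v in zip(shapes_u, shapes_v):
        u = np.asarray(u, dtype=bool)
        v = np.asarray(v, dtype=bool)
        if u.shape != v.shape:
            raise ValueError("masks must share a grid")
        denom = int(u.sum()) + int(v.sum())
        if denom == 0:
            warnings.warn("both masks empty for one angle; term counted as 0")
            terms.append(0.0)
        else:
            terms.append(2.0 * int((u & v).sum()) / denom)
    return float(np.mean(terms))


def dice_clouds(cloud_u: PointCloud4D, cloud_v: PointCloud4D,
                x_range: tuple[float, float], n_angles: int = 180,
                raster: float = 0.05, bin_width: float = 0.25,
                q: float = 0.9, y_half: float = 1.6) -> float:
    """Dice overlap of two clouds' envelope silhouettes over ``n_angles``
    projection angles on a shared raster.

    Envelope-based silhouettes are rotationally symmetric, so each angle
    contributes an identical term; the masks are still built and averaged
    per angle to keep the estimator's definition explicit.
    """
    env_u = envelope(cloud_u, bin_width=bin_width, q=q, x_range=x_range)
    env_v = envelope(cloud_v, bin_width=bin_width, q=q, x_range=x_range)
    angles = np.arange(n_angles) * (360.0 / max(n_angles, 1)) % 360.0
    mask_u = projected_shape(env_u, 0.0, raster, x_range, y_half)
    mask_v = projected_shape(env_v, 0.0, raster, x_range, y_half)
    return dice([mask_u] * len(angles), [mask_v] * len(angles))


def stenosis_length(env: EnvelopeModel, mode: str = "single") -> float:
    """Axial extent of the envelope dip at the half level.

    The half level is the midpoint between the body plateau (robust upper
    quantile of the envelope) and the minimum radius; crossings are
    located by linear interpolation between bins.  ``mode="single"``
    returns the widest dip, ``mode="sum-of-two"`` the sum of the two
    widest (back-and-forth motion images the narrowing twice).
    """
    if mode not in ("single", "sum-of-two"):
        raise ValueError(f"unknown mode {mode!r}")
    x = env.x_centers
    r = env.radius
    body = float(np.quantile(r, 0.95))
    r_min = float(r.min())
    if body - r_min < 1e-9 or r_min >= body - 1e-9:
        raise ValueError("envelope has no dip")
    half = 0.5 * (body + r_min)
    below = r < half
    if not below.any():
        raise ValueError("envelope has no dip below the half level")
    # contiguous runs of below-half bins, with sub-bin crossing positions
    runs = []
    i = 0
    n = len(r)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        if i > 0:
            frac = (half - r[i - 1]) / (r[i] - r[i - 1])
            x_lo = x[i - 1] + frac * (x[i] - x[i - 1])
        else:
            x_lo = x[0] - env.bin_width / 2
        if j < n - 1:
            frac = (half - r[j]) / (r[j + 1] - r[j])
            x_hi = x[j] + frac * (x[j + 1] - x[j])
        else:
            x_hi = x[-1] + env.bin_width / 2
        runs.append(x_hi - x_lo)
        i = j + 1
    runs.sort(reverse=True)
    if mode == "single":
        return float(runs[0])
    return float(sum(runs[:2]))


def trajectory_errors(traj: Trajectory4D, profile: MotionProfile,
                      sync: SyncInfo,
                      segments: list[tuple[float, float]] | None = None
                      ) -> TrackingErrorReport:
    """Positional and velocity errors of a tracked trajectory.

    MAE and SD are computed on ``|x_tracked - x_true|`` over valid samples
    within ``[t_m1, t_m2]``; the true position comes from the motion
    profile shifted to start at ``t_oct0``.  Per segment (default: the
    profile's own segments, clipped to the tracked window) a least-squares
    line is fitted to each coordinate over time; the fitted speed is the
    norm of the slope vector, compared against the segment's true speed.
    Segments with fewer than 2 samples are skipped.
    """
    sel = traj.valid & (traj.timestamps >= sync.t_m1) \
        & (traj.timestamps <= sync.t_m2)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 valid samples in the tracked window")
    t = traj.timestamps[sel]
    p = traj.positions[sel]
    x_true = profile.position_at(t - sync.t_oct0)
    err = np.abs(p[:, 0] - x_true)
    mae = float(err.mean())
    sd = float(err.std(ddof=0))

    if segments is None:
        bt, _ = profile.breakpoints
        segments = [(sync.t_oct0 + bt[i], sync.t_oct0 + bt[i + 1])
                    for i in range(len(bt) - 1)]
    seg_reports = []
    for i, (t0, t1) in enumerate(segments):
        m = (t >= t0) & (t <= t1)
        v_true = abs(profile.velocity_at(0.5 * (t0 + t1) - sync.t_oct0))
        if m.sum() < 2:
            seg_reports.append({"segment": i + 1, "n": int(m.sum()),
                                "skipped": True})
            continue
        slopes = [np.polyfit(t[m], p[m, a], 1)[0] for a in range(3)]
        speed = float(np.linalg.norm(slopes))
        ae = abs(speed - v_true)
        seg_err = np.abs(p[m, 0] - x_true[m])
        seg_reports.append({
            "segment": i + 1, "n": int(m.sum()), "skipped": False,
            "mae": float(seg_err.mean()), "sd": float(seg_err.std(ddof=0)),
            "v_true": v_true, "v_fit": speed, "velocity_ae": float(ae),
            "velocity_re": float(ae / v_true) if v_true > 0 else np.nan,
        })
    return TrackingErrorReport(mae=mae, sd=sd, n_samples=int(sel.sum()),
                               segments=seg_reports)
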