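"""Phantom geometry, catheter motion profiles and synthetic bimodal data.

Everything downstream consumes data produced here: a parametric straight
vessel with a central narrowing (the ground truth), piecewise
constant-velocity catheter motion, volumetric marker-image time series
and rotational A-scan catheter-to-wall distance streams.

Coordinate conventions
----------------------
* ``x`` is the pullback axis in millimetres, continuous world coordinates.
* Voxel index ``i`` maps to the world coordinate ``origin + (i + 0.5) *
  voxel_size`` (voxel-centre convention, 0-based indices).
* Pullback velocities are signed; pulling back decreases ``x``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomGeometry",
    "MotionProfile",
    "AcquisitionConstants",
    "ImageSeries4D",
    "AScanSeries",
    "PointCloud4D",
    "make_profile",
    "ground_truth_cloud",
    "simulate_mpi_series",
    "simulate_ascans",
    "segment_boundary",
    "V0",
    "V1",
    "PROFILE_NAMES",
]

#: Nominal pullback velocity [mm/s] (signed; pullback decreases x).
V0 = -1.25
#: Reduced velocity used in the middle segment of the bending profile [mm/s].
V1 = -0.625

PROFILE_NAMES = ("SP", "BA", "HBA")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomGeometry:
    """Straight vessel with a rotationally symmetric narrowing.

    The inner radius as a function of the axial coordinate is a plateau at
    ``body_inner_radius`` with a dip to ``stenosis_inner_radius`` of axial
    extent ``stenosis_length`` centred at ``stenosis_center_x``; the radius
    ramps linearly between the two plateaus over ``transition_length``.
    """

    body_inner_radius: float = 1.25
    body_length: float = 20.0
    stenosis_center_x: float = 12.5
    stenosis_length: float = 1.5
    stenosis_inner_radius: float = 0.75
    transition_length: float = 0.5

    def __post_init__(self) -> None:
        if not self.stenosis_inner_radius < self.body_inner_radius:
            raise ValueError("stenosis radius must be smaller than body radius")
        if not 0 < self.stenosis_length < self.body_length:
            raise ValueError("stenosis length must lie in (0, body_length)")
        lo = self.stenosis_center_x - self.stenosis_length / 2
        hi = self.stenosis_center_x + self.stenosis_length / 2
        if lo < 0 or hi > self.body_length:
            raise ValueError("stenosis must lie fully inside the phantom body")
        if self.transition_length < 0:
            raise ValueError("transition_length must be >= 0")

    def radius_at(self, x):
        """Inner wall radius [mm] at axial coordinate(s) ``x``.

        Outside ``[0, body_length]`` the body plateau is extended, which
        keeps simulated distance streams defined while the catheter is
        parked outside the phantom.
        """
        x = np.asarray(x, dtype=float)
        d = np.abs(x - self.stenosis_center_x) - self.stenosis_length / 2.0
        if self.transition_length > 1e-12:
            frac = np.clip(d / self.transition_length, 0.0, 1.0)
        else:
            frac = (d > 0).astype(float)
        r = self.stenosis_inner_radius + frac * (
            self.body_inner_radius - self.stenosis_inner_radius
        )
        return r if r.ndim else float(r)


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionProfile:
    """Piecewise constant-velocity 1D motion along the pullback axis.

    ``segments`` is an ordered tuple of ``(signed velocity mm/s,
    distance mm)``; each segment lasts ``distance / |velocity|`` seconds.
    Before ``t = 0`` and after the total duration the catheter is parked.
    """

    segments: tuple[tuple[float, float], ...]
    start_x: float = 22.5
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile needs at least one segment")
        for v, d in self.segments:
            if d <= 0:
                raise ValueError("segment distance must be > 0")
            if v == 0:
                raise ValueError("zero-velocity segment has undefined duration")

    @property
    def durations(self) -> np.ndarray:
        return np.array([d / abs(v) for v, d in self.segments])

    @property
    def duration(self) -> float:
        return float(self.durations.sum())

    @property
    def breakpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and positions at segment boundaries (length n+1 each)."""
        t = np.concatenate(([0.0], np.cumsum(self.durations)))
        dx = np.array([math.copysign(d, v) for v, d in self.segments])
        x = self.start_x + np.concatenate(([0.0], np.cumsum(dx)))
        return t, x

    @property
    def net_displacement(self) -> float:
        return float(sum(math.copysign(d, v) for v, d in self.segments))

    @property
    def path_length(self) -> float:
        return float(sum(d for _, d in self.segments))

    def position_at(self, t):
        """Axial position [mm] at time(s) ``t`` seconds after motion start."""
        bt, bx = self.breakpoints
        t = np.asarray(t, dtype=float)
        pos = np.interp(np.clip(t, 0.0, self.duration), bt, bx)
        return pos if pos.ndim else float(pos)

    def velocity_at(self, t):
        """Signed velocity [mm/s] at time(s) ``t``; zero outside the motion."""
        bt, _ = self.breakpoints
        t = np.asarray(t, dtype=float)
        seg = np.searchsorted(bt[1:-1], t, side="right")
        vels = np.array([v for v, _ in self.segments])
        out = vels[seg]
        out = np.where((t < 0) | (t > self.duration), 0.0, out)
        return out if out.ndim else float(out)


def make_profile(name: str, **overrides) -> MotionProfile:
    """Build a preset motion profile (``SP``, ``BA``, ``HBA``) or a custom one.

    Presets (v0 = -1.25 mm/s, v1 = -0.625 mm/s):

    * ``SP``  — constant pullback, one 25 mm segment at v0.
    * ``BA``  — 10 mm at v0, 5 mm at v1 (catheter stuck), 10 mm at v0.
    * ``HBA`` — 15 mm back, 5 mm forward, 15 mm back, all at |v0|.

    ``overrides`` may replace ``start_x``, ``v0``, ``v1`` or supply
    ``segments`` for ``name="custom"``.
    """
    v0 = overrides.pop("v0", V0)
    v1 = overrides.pop("v1", V1)
    start_x = overrides.pop("start_x", 22.5)
    segments = overrides.pop("segments", None)
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    presets = {
        "SP": ((v0, 25.0),),
        "BA": ((v0, 10.0), (v1, 5.0), (v0, 10.0)),
        "HBA": ((v0, 15.0), (-v0, 5.0), (v0, 15.0)),
    }
    if name in presets:
        if segments is not None:
            raise ValueError("segments override only allowed for name='custom'")
        return MotionProfile(presets[name], start_x=start_x, name=name)
    if name == "custom":
        if segments is None:
            raise ValueError("custom profile requires explicit segments")
        return MotionProfile(tuple(tuple(s) for s in segments),
                             start_x=start_x, name="custom")
    raise ValueError(f"unknown profile preset {name!r}")


# ---------------------------------------------------------------------------
# acquisition constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConstants:
    """Fixed acquisition rates and geometry of the two devices.

    The volumetric device produces frames every ``imaging_period_ms``; the
    rotational device acquires depth profiles at ``f_oct`` while rotating
    at ``f_rot``.  The motion and A-scan acquisition start
    ``trigger_delay_s`` after the volumetric trigger.
    """

    f_oct: float = 91_000.0
    f_rot: float = 6.25
    f_mpi_raw: float = 46.43
    imaging_period_ms: float = 21.54
    block_avg_factor: int = 2
    axial_fov_mm: float = 2.66
    samples_per_ascan: int = 512
    pixel_spacing_um: float = 4.5
    trigger_delay_s: float = 1.0

    def __post_init__(self) -> None:
        if self.block_avg_factor < 1:
            raise ValueError("block_avg_factor must be >= 1")
        if abs(self.f_mpi_raw - 1000.0 / self.imaging_period_ms) > 0.01:
            raise ValueError("frame rate inconsistent with imaging period")

    @property
    def f_mpi(self) -> float:
        """Frame rate of the tracking input after temporal block averaging."""
        return self.f_mpi_raw / self.block_avg_factor

    @property
    def pixel_spacing_mm(self) -> float:
        return self.pixel_spacing_um * 1e-3

    @property
    def theta0_deg(self) -> float:
        """Rotation angle between consecutive A-scans [deg]."""
        return 360.0 * self.f_rot / self.f_oct

    def pitch(self, v0: float) -> float:
        """Axial advance per A-scan [mm] at constant velocity ``v0``."""
        return v0 / self.f_oct

    def positions_per_rotation(self) -> int:
        """Tracked catheter positions available per catheter rotation."""
        return math.ceil(self.f_mpi / self.f_rot)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class ImageSeries4D:
    """Time-ordered stack of 3D scalar voxel grids with spatial metadata."""

    frames: np.ndarray            # (T, X, Y, Z), intensities >= 0
    voxel_size: np.ndarray        # (3,) mm
    origin: np.ndarray            # (3,) mm, world coordinate of grid corner
    timestamps: np.ndarray        # (T,) s, uniform
    frame_rate: float             # Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be a (T, X, Y, Z) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-9:
                raise ValueError("timestamps must be uniform within 1e-9 s")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along ``axis``."""
        n = self.frames.shape[1 + axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]


@dataclass
class AScanSeries:
    """Stream of per-A-scan wall distances (and optionally raw profiles).

    ``timestamps`` are seconds relative to the start of the A-scan
    acquisition; the absolute placement on the shared time axis is handled
    by the synchronisation metadata at reconstruction time.
    """

    timestamps: np.ndarray                 # (n,) s, uniform at 1/f_oct
    r: np.ndarray | None                   # (n,) mm catheter-to-wall distance
    valid: np.ndarray                      # (n,) bool
    f_oct: float
    f_rot: float
    pixel_spacing_mm: float
    profiles: np.ndarray | None = None     # (n, samples) raw intensities
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.r is not None:
            self.r = np.asarray(self.r, dtype=float)
            if len(self.r) != len(self.timestamps):
                raise ValueError("r and timestamps length mismatch")
        if len(self.valid) != len(self.timestamps):
            raise ValueError("valid and timestamps length mismatch")

    def __len__(self) -> int:
        return len(self.timestamps)

    def angles_deg(self) -> np.ndarray:
        """Rotation angle of each A-scan [deg], zero origin at index 0."""
        return 360.0 * self.f_rot * self.timestamps


@dataclass
class PointCloud4D:
    """Timestamped 3D boundary points of a volume reconstruction."""

    points: np.ndarray    # (n, 3) mm
    times: np.ndarray     # (n,) s, non-decreasing in acquisition order
    method: str = "ground-truth"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.points):
            raise ValueError("one time per point required")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def radii(self) -> np.ndarray:
        """Distance of each point from the pullback axis."""
        return np.hypot(self.points[:, 1], self.points[:, 2])

    def crop_x(self, low: float, high: float) -> "PointCloud4D":
        keep = (self.points[:, 0] >= low) & (self.points[:, 0] <= high)
        return PointCloud4D(self.points[keep], self.times[keep], self.method)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def ground_truth_cloud(phantom: PhantomGeometry, x_step: float = 0.1,
                       n_angles: int = 32,
                       x_range: tuple[float, float] | None = None
                       ) -> PointCloud4D:
    """Sample the inner wall surface on a regular axial/angular grid."""
    if x_step <= 0:
        raise ValueError("x_step must be > 0")
    if n_angles < 4:
        raise ValueError("n_angles must be >= 4")
    lo, hi = x_range if x_range is not None else (0.0, phantom.body_length)
    xs = np.arange(lo, hi + x_step / 2, x_step)
    ang = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    r = phantom.radius_at(xs)
    X = np.repeat(xs, n_angles)
    R = np.repeat(r, n_angles)
    A = np.tile(ang, len(xs))
    pts = np.column_stack([X, R * np.cos(A), R * np.sin(A)])
    return PointCloud4D(pts, np.zeros(len(pts)), method="ground-truth")


def simulate_mpi_series(profile: MotionProfile,
                        grid_shape: tuple[int, int, int] = (35, 25, 13),
                        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                        origin: tuple[float, float, float] = (-5.0, -12.5, -6.5),
                        psf_sigma: float = 1.5,
                        noise_sd: float = 0.0,
                        duration: float | None = None,
                        frame_rate: float | None = None,
                        motion_start: float = 1.0,
                        marker_yz: tuple[float, float] = (0.0, 0.0),
                        amplitude: float = 1.0,
                        seed: int = 0) -> ImageSeries4D:
    """Simulate the volumetric marker-image series of a pullback run.

    Each frame holds an isotropic Gaussian blob of scale ``psf_sigma`` (mm)
    centred at the true catheter-tip position at that frame's timestamp —
    the compact bright appearance of the reconstructed marker — plus
    non-negative clipped Gaussian background noise.  Frame 0 is acquired at
    the trigger (t = 0); the motion starts at ``motion_start`` seconds.
    Bit-reproducible for a fixed seed.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    consts = AcquisitionConstants()
    if frame_rate is None:
        frame_rate = consts.f_mpi_raw
    if duration is None:
        duration = motion_start + profile.duration + 0.5
    if duration < profile.duration:
        raise ValueError("duration must cover the motion profile")
    n_frames = int(np.floor(duration * frame_rate))
    ts = np.arange(n_frames) / frame_rate
    xs = profile.position_at(ts - motion_start)

    voxel_size = np.asarray(voxel_size, float)
    origin = np.asarray(origin, float)
    coords = [origin[a] + (np.arange(grid_shape[a]) + 0.5) * voxel_size[a]
              for a in range(3)]
    centers = np.column_stack([xs,
                               np.full(n_frames, marker_yz[0]),
                               np.full(n_frames, marker_yz[1])])

    lo = origin
    hi = origin + np.asarray(grid_shape) * voxel_size
    outside = bool(np.any(centers < lo) or np.any(centers > hi))

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, *grid_shape))
    inv2s2 = 1.0 / (2.0 * psf_sigma ** 2)
    for i in range(n_frames):
        gx = np.exp(-((coords[0] - centers[i, 0]) ** 2) * inv2s2)
        gy = np.exp(-((coords[1] - centers[i, 1]) ** 2) * inv2s2)
        gz = np.exp(-((coords[2] - centers[i, 2]) ** 2) * inv2s2)
        frames[i] = amplitude * np.einsum("i,j,k->ijk", gx, gy, gz)
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)

    meta = {
        "psf_sigma": psf_sigma,
        "noise_sd": noise_sd,
        "seed": seed,
        "motion_start": motion_start,
        "profile": profile.name,
        "trajectory_outside_grid": outside,
    }
    if outside:
        warnings.warn("marker trajectory leaves the voxel grid; blob truncated")
    return ImageSeries4D(frames, voxel_size, origin, ts, frame_rate, meta)


def _wall_distance(R, offset, phi):
    """Distance from an off-axis ray origin to a circle of radius R.

    ``offset`` is the catheter-axis displacement from the lumen centre and
    ``phi`` the ray angle measured from the displacement direction.
    """
    s = offset * np.sin(phi)
    return np.sqrt(np.maximum(R ** 2 - s ** 2, 0.0)) - offset * np.cos(phi)


def simulate_ascans(phantom: PhantomGeometry, profile: MotionProfile,
                    consts: AcquisitionConstants | None = None,
                    catheter_offset: float = 0.0,
                    offset_angle_deg: float = 0.0,
                    r_noise_sd: float = 0.0,
                    seed: int = 0,
                    emit_profiles: bool = False,
                    peak_width_px: float = 3.0) -> AScanSeries:
    """Simulate the per-A-scan catheter-to-wall distance stream.

    A-scan ``k`` is taken at ``t_k = k / f_oct`` (relative to motion start)
    at rotation angle ``360 * f_rot * t_k``; its distance is measured from
    the (possibly off-centre) catheter axis at the current axial position
    to the wall along that angle, plus zero-mean Gaussian noise.  With
    ``emit_profiles`` a raw intensity profile with a single wall peak at
    the sample index ``r / pixel_spacing`` is attached per A-scan.
    """
    consts = consts or AcquisitionConstants()
    if abs(catheter_offset) >= phantom.stenosis_inner_radius:
        raise ValueError("catheter offset too large: would touch the wall "
                         "inside the stenosis")
    n = int(np.floor(profile.duration * consts.f_oct))
    t = np.arange(n) / consts.f_oct
    x = profile.position_at(t)
    R = phantom.radius_at(x)
    if catheter_offset != 0.0:
        phi = 2 * np.pi * consts.f_rot * t - np.deg2rad(offset_angle_deg)
        r = _wall_distance(R, catheter_offset, phi)
    else:
        r = np.asarray(R, float).copy()
    rng = np.random.default_rng(seed)
    if r_noise_sd > 0:
        r = r + rng.normal(0.0, r_noise_sd, size=n)
    series = AScanSeries(
        timestamps=t, r=r, valid=np.ones(n, dtype=bool),
        f_oct=consts.f_oct, f_rot=consts.f_rot,
        pixel_spacing_mm=consts.pixel_spacing_mm,
        meta={"profile": profile.name, "seed": seed,
              "catheter_offset": catheter_offset, "r_noise_sd": r_noise_sd},
    )
    if emit_profiles:
        idx = np.arange(consts.samples_per_ascan)
        peak = r / consts.pixel_spacing_mm
        prof = np.exp(-((idx[None, :] - peak[:, None]) ** 2)
                      / (2.0 * peak_width_px ** 2)).astype(np.float32)
        series.profiles = prof
    return series


def segment_boundary(series: AScanSeries, threshold: float = 0.5,
                     dead_zone: int = 10) -> AScanSeries:
    """Fill ``r`` from raw profiles by first-peak detection.

    The wall distance of each A-scan is the index of the first local
    maximum above ``threshold`` beyond ``dead_zone`` samples, scaled by the
    pixel spacing.  A-scans without such a peak are marked invalid.
    """
    if series.profiles is None:
        raise ValueError("series carries no raw profiles")
    p = np.asarray(series.profiles, dtype=float)
    n, m = p.shape
    is_peak = np.zeros_like(p, dtype=bool)
    is_peak[:, 1:-1] = (p[:, 1:-1] >= p[:, :-2]) & (p[:, 1:-1] >= p[:, 2:]) \
        & (p[:, 1:-1] > threshold)
    is_peak[:, :dead_zone] = False
    any_peak = is_peak.any(axis=1)
    first = np.argmax(is_peak, axis=1)
    r = np.where(any_peak, first * series.pixel_spacing_mm, np.nan)
    return AScanSeries(
        timestamps=series.timestamps.copy(), r=r,
        valid=series.valid & any_peak,
        f_oct=series.f_oct, f_rot=series.f_rot,
        pixel_spacing_mm=series.pixel_spacing_mm,
        profiles=series.profiles,
        meta={**series.meta, "segmentation": "first-peak",
              "threshold": threshold, "dead_zone": dead_zone},
    )
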