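"""Arrangement of A-scan wall distances into 4D boundary point clouds.

Two methods: the input-parameter (IP) method assumes perfectly constant
pullback and rotation speeds and places A-scans on an ideal helix; the
marker-tracking (MT) method distributes A-scans along the tracked axial
catheter trajectory using the trigger-based time synchronisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom_sim import AcquisitionConstants, AScanSeries, PointCloud4D
from .tracking import Trajectory4D

__all__ = ["SyncInfo", "PointCloud4D", "make_sync",
           "reconstruct_ip", "reconstruct_mt"]


@dataclass(frozen=True)
class SyncInfo:
    """Shared time axis of the two devices.

    All times are seconds on the volumetric device's clock.  The motion
    and A-scan acquisition start ``trigger_delay`` after the trigger, so
    A-scan ``k`` is acquired at ``t_oct0 + k / f_oct``.
    """

    t_trigger: float
    t_oct0: float
    t_m1: float
    t_m2: float
    t_oct_end: float
    t_mpi_end: float

    def __post_init__(self) -> None:
        ok = (self.t_trigger < self.t_oct0 <= self.t_m1 < self.t_m2
              <= self.t_oct_end <= self.t_mpi_end)
        if not ok:
            raise ValueError("sync times must be ordered "
                             "trigger < oct0 <= m1 < m2 <= oct_end <= mpi_end")

    def ascan_index(self, t: float, f_oct: float) -> int:
        """Index of the A-scan acquired at absolute time ``t``."""
        return int(round((t - self.t_oct0) * f_oct))


def make_sync(t_trigger: float, consts: AcquisitionConstants,
              traj: Trajectory4D, n_ascans: int | None = None) -> SyncInfo:
    """Derive the synchronisation record from the trigger and a trajectory.

    ``t_oct0`` is the trigger time plus the fixed trigger delay; the FoV
    entry/exit times are copied from the trajectory's m1/m2 samples.
    """
    if traj.m1_index is None or traj.m2_index is None:
        raise ValueError("trajectory has no m1/m2 marks")
    t_oct0 = t_trigger + consts.trigger_delay_s
    t_mpi_end = float(traj.timestamps[-1])
    if n_ascans is not None:
        t_oct_end = max(t_oct0 + n_ascans / consts.f_oct, traj.t_m2)
    else:
        t_oct_end = max(t_mpi_end, traj.t_m2)
    t_mpi_end = max(t_mpi_end, t_oct_end)
    return SyncInfo(t_trigger, t_oct0, traj.t_m1, traj.t_m2,
                    t_oct_end, t_mpi_end)


def _cylinder_points(x, r, angle_rad):
    return np.column_stack([x, r * np.cos(angle_rad), r * np.sin(angle_rad)])


def reconstruct_ip(ascans: AScanSeries, consts: AcquisitionConstants,
                   v0: float, start_x: float) -> PointCloud4D:
    """Ideal-helix reconstruction from assumed constant kinematics.

    A-scan k sits at axial position ``start_x + k * v0 / f_oct`` and angle
    ``k * 360 * f_rot / f_oct``, at radius ``r_k``.  A-scans with missing
    or invalid r are skipped.  Point times are seconds relative to the
    start of the A-scan acquisition.
    """
    if ascans.r is None:
        raise ValueError("A-scan series has no wall distances")
    keep = ascans.valid & np.isfinite(ascans.r)
    k = np.flatnonzero(keep)
    t = k / consts.f_oct
    x = start_x + v0 * t
    phi = 2.0 * np.pi * consts.f_rot * t
    pts = _cylinder_points(x, ascans.r[k], phi)
    return PointCloud4D(pts, t, method="IP")


def reconstruct_mt(ascans: AScanSeries, traj: Trajectory4D, sync: SyncInfo,
                   consts: AcquisitionConstants) -> PointCloud4D:
    """Reconstruction along the tracked axial catheter trajectory.

    Only valid trajectory samples with times in ``[t_m1, t_m2]`` are used.
    Between two consecutive tracked positions the A-scans acquired in that
    interval are distributed equidistantly in x (linear interpolation of x
    over the uniformly spaced A-scan times); only the x coordinate of the
    trajectory is used.  A-scans outside ``[t_m1, t_m2]`` are excluded.
    Angles advance by the fixed per-A-scan rotation increment regardless
    of axial motion.  Point times are absolute (volumetric clock).
    """
    if ascans.r is None:
        raise ValueError("A-scan series has no wall distances")
    sel = traj.valid & (traj.timestamps >= sync.t_m1) \
        & (traj.timestamps <= sync.t_m2)
    tt = traj.timestamps[sel]
    xx = traj.positions[sel, 0]
    if len(tt) < 2:
        raise ValueError("no usable trajectory overlap with the A-scan window")
    if np.any(np.diff(tt) <= 0):
        raise ValueError("trajectory timestamps must be sorted")
    k = np.arange(len(ascans))
    t_abs = sync.t_oct0 + k / consts.f_oct
    keep = ascans.valid & np.isfinite(ascans.r) \
        & (t_abs >= sync.t_m1) & (t_abs <= sync.t_m2)
    k = k[keep]
    x = np.interp(t_abs[keep], tt, xx)
    phi = 2.0 * np.pi * consts.f_rot * (k / consts.f_oct)
    pts = _cylinder_points(x, ascans.r[keep], phi)
    return PointCloud4D(pts, t_abs[keep], method="MT")
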