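"""File formats.

* Image series: HDF5 with one dataset ``/frames`` of shape (T, X, Y, Z)
  and attributes ``voxel_size``, ``origin``, ``frame_rate`` plus a
  ``/timestamps`` dataset (a self-defined, documented layout).
* Trajectories, A-scan streams and point clouds: CSV with headers.
* Run configuration: YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .phantom_sim import AScanSeries, ImageSeries4D, PointCloud4D
from .tracking import Trajectory4D

__all__ = [
    "save_series", "load_series",
    "trajectory_to_csv", "trajectory_from_csv",
    "cloud_to_csv", "cloud_from_csv",
    "ascans_to_csv", "ascans_from_csv",
    "load_config",
]


def save_series(series: ImageSeries4D, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=series.frames)
        d.attrs["voxel_size"] = series.voxel_size
        d.attrs["origin"] = series.origin
        d.attrs["frame_rate"] = series.frame_rate
        f.create_dataset("timestamps", data=series.timestamps)
        for k, v in series.meta.items():
            if isinstance(v, (int, float, str, bool)):
                f.attrs[k] = v


def load_series(path: str | Path) -> ImageSeries4D:
    with h5py.File(path, "r") as f:
        d = f["frames"]
        return ImageSeries4D(
            frames=d[...],
            voxel_size=d.attrs["voxel_size"],
            origin=d.attrs["origin"],
            timestamps=f["timestamps"][...],
            frame_rate=float(d.attrs["frame_rate"]),
            meta=dict(f.attrs),
        )


def trajectory_to_csv(traj: Trajectory4D, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": traj.timestamps,
        "x_mm": traj.positions[:, 0],
        "y_mm": traj.positions[:, 1],
        "z_mm": traj.positions[:, 2],
        "valid": traj.valid.astype(int),
    })
    df.to_csv(path, index=False)


def trajectory_from_csv(path: str | Path) -> Trajectory4D:
    df = pd.read_csv(path)
    return Trajectory4D(
        timestamps=df["time_s"].to_numpy(),
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
    )


def cloud_to_csv(cloud: PointCloud4D, path: str | Path) -> None:
    df = pd.DataFrame({
        "x_mm": cloud.points[:, 0],
        "y_mm": cloud.points[:, 1],
        "z_mm": cloud.points[:, 2],
        "t_s": cloud.times,
    })
    df.to_csv(path, index=False)


def cloud_from_csv(path: str | Path, method: str = "custom") -> PointCloud4D:
    df = pd.read_csv(path)
    return PointCloud4D(df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                        df["t_s"].to_numpy(), method=method)


def ascans_to_csv(series: AScanSeries, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": series.timestamps,
        "r_mm": series.r if series.r is not None
        else np.full(len(series), np.nan),
        "valid": series.valid.astype(int),
    })
    df.to_csv(path, index=False)


def ascans_from_csv(path: str | Path, f_oct: float = 91_000.0,
                    f_rot: float = 6.25,
                    pixel_spacing_mm: float = 4.5e-3) -> AScanSeries:
    df = pd.read_csv(path)
    return AScanSeries(
        timestamps=df["time_s"].to_numpy(),
        r=df["r_mm"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        f_oct=f_oct, f_rot=f_rot, pixel_spacing_mm=pixel_spacing_mm,
    )


def load_config(path: str | Path):
    """Load a YAML run configuration into a RunConfig."""
    from .pipeline import RunConfig
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "crop_x" in raw:
        raw["crop_x"] = tuple(raw["crop_x"])
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    return RunConfig(**raw)
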