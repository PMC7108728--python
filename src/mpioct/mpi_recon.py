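"""Desk-scale frequency-space style image reconstruction.

A synthetic system matrix maps voxel-wise marker concentration to a
measurement vector; images are recovered with a Tikhonov-regularised
Kaczmarz row-action solver.  Temporal block averaging of image series
lives here as well since it is part of the reconstruction chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .phantom_sim import ImageSeries4D

__all__ = [
    "SystemMatrix",
    "Measurement",
    "ReconParams",
    "build_system_matrix",
    "lambda0",
    "kaczmarz_solve",
    "block_average",
]


@dataclass
class SystemMatrix:
    """M x N linear response map; column j is the response to a unit
    concentration in voxel j."""

    entries: np.ndarray
    grid_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if self.entries.ndim != 2 or min(self.entries.shape) < 1:
            raise ValueError("entries must be a non-empty 2D matrix")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("entries must be finite")
        if int(np.prod(self.grid_shape)) != self.entries.shape[1]:
            raise ValueError("grid_shape does not match number of columns")

    @property
    def m_rows(self) -> int:
        return self.entries.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.entries.shape[1]


@dataclass
class Measurement:
    """Length-M measurement vector."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        if not np.all(np.isfinite(self.u)):
            raise ValueError("measurement must be finite")


@dataclass(frozen=True)
class ReconParams:
    iterations: int = 3
    lambda_rel: float = 1e-3
    enforce_nonneg: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.lambda_rel < 0:
            raise ValueError("lambda_rel must be >= 0")


def _blur_1d(n: int, sigma: float) -> np.ndarray:
    if sigma <= 1e-12:
        return np.eye(n)
    col = np.exp(-np.arange(n) ** 2 / (2.0 * sigma ** 2))
    return toeplitz(col)


def build_system_matrix(grid_shape: tuple[int, ...], psf_sigma: float,
                        seed: int = 0, m_rows: int | None = None,
                        mixing: str = "random") -> SystemMatrix:
    """Build a synthetic calibration-style system matrix.

    The forward model is a separable Gaussian blur of scale ``psf_sigma``
    (voxels) followed by a fixed measurement mixing: ``mixing="random"``
    projects the blurred image onto ``m_rows`` seeded random measurement
    rows (default ``2 N``), ``mixing="identity"`` keeps the blurred image
    itself.  Column j equals the forward model applied to the delta image
    e_j, so columns of well-separated voxels are nearly orthogonal.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if any(s < 1 for s in grid_shape):
        raise ValueError("grid_shape must be positive")
    blur = np.array([[1.0]])
    for n in grid_shape:
        blur = np.kron(blur, _blur_1d(n, psf_sigma)) if blur.size > 1 \
            else _blur_1d(n, psf_sigma)
    n_vox = int(np.prod(grid_shape))
    if mixing == "identity":
        entries = blur
    elif mixing == "random":
        m = m_rows if m_rows is not None else 2 * n_vox
        rng = np.random.default_rng(seed)
        mix = rng.standard_normal((m, n_vox)) / np.sqrt(m)
        entries = mix @ blur
    else:
        raise ValueError(f"unknown mixing {mixing!r}")
    return SystemMatrix(entries, grid_shape)


def lambda0(S: SystemMatrix) -> float:
    """Reference regularisation scale trace(S^H S) / N."""
    e = S.entries
    if e.size == 0:
        raise ValueError("empty system matrix")
    return float(np.real(np.einsum("ij,ij->", np.conj(e), e)) / S.n_voxels)


def kaczmarz_solve(S: SystemMatrix, u: Measurement | np.ndarray,
                   params: ReconParams | None = None) -> np.ndarray:
    """Solve ``min ||S c - u||^2 + lambda ||c||^2`` by regularised Kaczmarz.

    ``lambda = lambda_rel * lambda0(S)``.  Rows are visited sequentially;
    each sweep performs one row-action update per measurement row on the
    augmented system.  With ``enforce_nonneg`` the solution is clipped to
    be non-negative after every sweep (concentrations are physical).
    """
    params = params or ReconParams()
    A = S.entries
    b = u.u if isinstance(u, Measurement) else np.asarray(u)
    if b.shape != (A.shape[0],):
        raise ValueError("measurement length does not match matrix rows")
    energies = np.real(np.einsum("ij,ij->i", np.conj(A), A))
    if not np.any(energies > 0):
        raise ValueError("all-zero system matrix")
    lam = params.lambda_rel * lambda0(S)
    sql = np.sqrt(lam)
    dtype = np.result_type(A.dtype, b.dtype, float)
    c = np.zeros(A.shape[1], dtype=dtype)
    v = np.zeros(A.shape[0], dtype=dtype)
    for _ in range(params.iterations):
        for i in range(A.shape[0]):
            denom = energies[i] + lam
            if denom == 0:
                continue
            alpha = (b[i] - A[i] @ c - sql * v[i]) / denom
            c += alpha * np.conj(A[i])
            v[i] += alpha * sql
        if params.enforce_nonneg:
            c = np.clip(c.real, 0.0, None).astype(dtype)
    if params.enforce_nonneg:
        c = c.real
    return c


def block_average(series: ImageSeries4D, factor: int) -> ImageSeries4D:
    """Average consecutive frames in non-overlapping blocks of ``factor``.

    Output frame i is the mean of input frames ``[i*factor, (i+1)*factor)``;
    a trailing remainder is dropped.  The frame rate is divided by
    ``factor`` and each output timestamp is the mean of its constituents.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return series
    t_out = len(series) // factor
    if t_out == 0:
        raise ValueError("fewer frames than averaging factor")
    used = t_out * factor
    frames = series.frames[:used].reshape(t_out, factor,
                                          *series.grid_shape).mean(axis=1)
    ts = series.timestamps[:used].reshape(t_out, factor).mean(axis=1)
    return ImageSeries4D(frames, series.voxel_size.copy(),
                         series.origin.copy(), ts,
                         series.frame_rate / factor,
                         {**series.meta, "block_avg_factor": factor})
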