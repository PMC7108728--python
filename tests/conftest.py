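import numpy as np
import pytest

from mpioct.phantom_sim import (AcquisitionConstants, PhantomGeometry,
                                make_profile, simulate_mpi_series)


@pytest.fixture(scope="session")
def consts():
    return AcquisitionConstants()


@pytest.fixture(scope="session")
def phantom():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def sharp_phantom():
    """Phantom with near-instant shoulders (true FWHM ~ stenosis length)."""
    return PhantomGeometry(transition_length=0.05)


@pytest.fixture(scope="session")
def sp_profile():
    return make_profile("SP")


@pytest.fixture(scope="session")
def short_series():
    """Small noise-free image series over a 2 s pullback (fast tests)."""
    profile = make_profile("custom", segments=[(-1.25, 2.5)], start_x=14.0)
    return simulate_mpi_series(profile, grid_shape=(20, 15, 9),
                               origin=(2.0, -7.5, -4.5), psf_sigma=1.5,
                               noise_sd=0.0, motion_start=0.0,
                               duration=2.0, seed=0)


def gaussian_blob_frame(shape, center, sigma, voxel_size=(1.0, 1.0, 1.0),
                        origin=(0.0, 0.0, 0.0), amplitude=1.0):
    """Analytic separable Gaussian blob sampled at voxel centres."""
    voxel_size = np.asarray(voxel_size, float)
    origin = np.asarray(origin, float)
    axes = [origin[a] + (np.arange(shape[a]) + 0.5) * voxel_size[a]
            for a in range(3)]
    g = [np.exp(-((ax - c) ** 2) / (2 * sigma ** 2))
         for ax, c in zip(axes, center)]
    return amplitude * np.einsum("i,j,k->ijk", *g)
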