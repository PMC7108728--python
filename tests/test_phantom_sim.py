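import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpioct.phantom_sim import (AcquisitionConstants, PhantomGeometry,
                                ground_truth_cloud, make_profile,
                                segment_boundary, simulate_ascans,
                                simulate_mpi_series, AScanSeries)


# ---------------------------------------------------------------------------
# motion profiles
# ---------------------------------------------------------------------------

class TestMakeProfile:
    def test_sp_positions(self):
        p = make_profile("SP")
        assert p.position_at(0.0) == pytest.approx(22.5)
        assert p.position_at(20.0) == pytest.approx(22.5 - 25.0)
        assert p.duration == pytest.approx(20.0)

    def test_ba_segment_velocities(self):
        p = make_profile("BA")
        # segment 2 spans 8 s - 16 s (10/1.25 = 8 s, 5/0.625 = 8 s)
        assert p.velocity_at(12.0) == pytest.approx(-0.625)
        assert p.velocity_at(4.0) == pytest.approx(-1.25)
        assert p.velocity_at(20.0) == pytest.approx(-1.25)
        assert np.allclose(p.durations, [8.0, 8.0, 8.0])

    def test_hba_net_vs_path(self):
        p = make_profile("HBA")
        assert p.position_at(p.duration) - p.start_x == pytest.approx(-25.0)
        assert p.path_length == pytest.approx(35.0)

    def test_sp_ba_path_length(self):
        assert make_profile("SP").path_length == pytest.approx(25.0)
        assert make_profile("BA").path_length == pytest.approx(25.0)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            make_profile("XX")

    def test_zero_velocity_segment(self):
        with pytest.raises(ValueError):
            make_profile("custom", segments=[(0.0, 5.0)])

    def test_clamped_outside_motion(self):
        p = make_profile("SP")
        assert p.position_at(-3.0) == pytest.approx(p.start_x)
        assert p.position_at(99.0) == pytest.approx(p.start_x - 25.0)
        assert p.velocity_at(-1.0) == 0.0
        assert p.velocity_at(25.0) == 0.0

    @pytest.mark.parametrize("name", ["SP", "BA", "HBA"])
    def test_velocity_integral_matches_net_displacement(self, name):
        # midpoint Riemann sums per segment are exact for constant velocity
        p = make_profile(name)
        bt, _ = p.breakpoints
        total = 0.0
        for t0, t1 in zip(bt[:-1], bt[1:]):
            ts = np.linspace(t0, t1, 2001)
            mid = 0.5 * (ts[:-1] + ts[1:])
            total += np.sum(p.velocity_at(mid) * np.diff(ts))
        assert total == pytest.approx(p.net_displacement, abs=1e-9)


# ---------------------------------------------------------------------------
# phantom geometry / ground truth
# ---------------------------------------------------------------------------

class TestGroundTruth:
    def test_radii_at_plateaus(self, phantom):
        cloud = ground_truth_cloud(phantom, x_step=0.1, n_angles=16)
        at_sten = np.isclose(cloud.x, phantom.stenosis_center_x)
        assert np.allclose(cloud.radii[at_sten], 0.75)
        far = np.abs(cloud.x - phantom.stenosis_center_x) > 5.0
        assert np.allclose(cloud.radii[far], 1.25)

    def test_rotational_symmetry(self, phantom):
        cloud = ground_truth_cloud(phantom, x_step=0.5, n_angles=12)
        for xv in np.unique(cloud.x):
            r = cloud.radii[cloud.x == xv]
            assert np.ptp(r) < 1e-12

    def test_two_plateaus_plus_strict_transitions(self, phantom):
        cloud = ground_truth_cloud(phantom, x_step=0.05, n_angles=4)
        r = cloud.radii
        mid = (~np.isclose(r, 0.75)) & (~np.isclose(r, 1.25))
        assert np.isclose(r, 0.75).any() and np.isclose(r, 1.25).any()
        assert np.all((r[mid] > 0.75) & (r[mid] < 1.25))

    def test_invariants(self):
        with pytest.raises(ValueError):
            PhantomGeometry(stenosis_inner_radius=1.5)
        with pytest.raises(ValueError):
            PhantomGeometry(stenosis_center_x=0.1)


# ---------------------------------------------------------------------------
# volumetric marker simulation
# ---------------------------------------------------------------------------

class TestSimulateMpiSeries:
    def test_marker_at_voxel_center_is_argmax(self):
        # start_x 22.5 is a voxel centre of the default grid; the marker is
        # parked there until the motion starts at t = 1 s
        profile = make_profile("custom", segments=[(-1.25, 0.1)],
                               start_x=22.5)
        s = simulate_mpi_series(profile, noise_sd=0.0, duration=0.1,
                                motion_start=1.0, seed=0)
        idx = np.unravel_index(np.argmax(s.frames[0]), s.grid_shape)
        assert s.axis_coords(0)[idx[0]] == pytest.approx(22.5)
        assert s.axis_coords(1)[idx[1]] == pytest.approx(0.0)
        assert s.axis_coords(2)[idx[2]] == pytest.approx(0.0)

    def test_centroid_recovers_position(self):
        # oracle: intensity-weighted centroid of supra-threshold voxels of
        # an analytic Gaussian recovers the true centre to < 0.1 mm
        profile = make_profile("custom", segments=[(-1.25, 10.0)],
                               start_x=22.5)
        s = simulate_mpi_series(profile, noise_sd=0.0, duration=8.0,
                                motion_start=0.0, seed=0)
        for i in range(0, len(s), 50):
            t = s.timestamps[i]
            truth = np.array([profile.position_at(t), 0.0, 0.0])
            f = s.frames[i]
            mask = f >= 0.05 * f.max()
            idx = np.argwhere(mask)
            coords = s.origin + (idx + 0.5) * s.voxel_size
            w = f[mask]
            com = (coords * w[:, None]).sum(0) / w.sum()
            assert np.all(np.abs(com - truth) < 0.1)

    def test_frame_count_20s(self):
        profile = make_profile("SP")
        s = simulate_mpi_series(profile, duration=20.0, motion_start=0.0)
        assert len(s) in (928, 929)

    def test_deterministic_for_seed(self):
        profile = make_profile("custom", segments=[(-1.25, 1.0)])
        a = simulate_mpi_series(profile, noise_sd=0.05, seed=7,
                                duration=1.0, motion_start=0.0)
        b = simulate_mpi_series(profile, noise_sd=0.05, seed=7,
                                duration=1.0, motion_start=0.0)
        assert np.array_equal(a.frames, b.frames)

    def test_noise_clipped_nonnegative(self):
        profile = make_profile("custom", segments=[(-1.25, 1.0)])
        s = simulate_mpi_series(profile, noise_sd=0.5, seed=1,
                                duration=1.0, motion_start=0.0)
        assert np.all(s.frames >= 0)

    def test_out_of_grid_flagged(self):
        profile = make_profile("custom", segments=[(-1.25, 1.0)],
                               start_x=100.0)
        with pytest.warns(UserWarning):
            s = simulate_mpi_series(profile, duration=1.0, motion_start=0.0)
        assert s.meta["trajectory_outside_grid"]


# ---------------------------------------------------------------------------
# A-scan simulation and boundary segmentation
# ---------------------------------------------------------------------------

class TestSimulateAscans:
    def test_centered_body_radius(self, phantom, consts):
        profile = make_profile("custom", segments=[(-1.25, 0.5)], start_x=5.0)
        a = simulate_ascans(phantom, profile, consts)
        assert np.allclose(a.r, 1.25)

    def test_centered_stenosis_radius(self, consts):
        ph = PhantomGeometry(transition_length=0.05)
        profile = make_profile("custom", segments=[(-1.25, 0.5)],
                               start_x=ph.stenosis_center_x + 0.25)
        a = simulate_ascans(ph, profile, consts)
        assert np.allclose(a.r, 0.75)

    def test_offset_oscillation_matches_quadratic_oracle(self, phantom,
                                                         consts):
        # oracle: positive root of r^2 + 2 d cos(phi) r + d^2 - R^2 = 0
        d, R = 0.3, 1.25
        profile = make_profile("custom", segments=[(-1.25, 0.25)], start_x=5.0)
        a = simulate_ascans(phantom, profile, consts, catheter_offset=d)
        one_rot = int(consts.f_oct / consts.f_rot)
        r = a.r[:one_rot]
        phi = 2 * np.pi * consts.f_rot * a.timestamps[:one_rot]
        for k in range(0, one_rot, 977):
            roots = np.roots([1.0, 2 * d * np.cos(phi[k]), d ** 2 - R ** 2])
            expected = roots[roots > 0][0]
            assert r[k] == pytest.approx(expected, abs=1e-9)
        assert r.min() == pytest.approx(R - d, abs=1e-6)
        assert r.max() == pytest.approx(R + d, abs=1e-6)

    def test_offset_too_large(self, phantom, consts):
        profile = make_profile("SP")
        with pytest.raises(ValueError):
            simulate_ascans(phantom, profile, consts, catheter_offset=0.8)

    def test_noise_deterministic(self, phantom, consts):
        profile = make_profile("custom", segments=[(-1.25, 0.25)], start_x=5.0)
        a = simulate_ascans(phantom, profile, consts, r_noise_sd=0.02, seed=3)
        b = simulate_ascans(phantom, profile, consts, r_noise_sd=0.02, seed=3)
        assert np.array_equal(a.r, b.r)


def _series_with_profiles(profiles, pixel_spacing_mm=4.5e-3):
    n = len(profiles)
    return AScanSeries(timestamps=np.arange(n) / 91_000.0, r=None,
                       valid=np.ones(n, bool), f_oct=91_000.0, f_rot=6.25,
                       pixel_spacing_mm=pixel_spacing_mm,
                       profiles=np.asarray(profiles, float))


class TestSegmentBoundary:
    def test_single_peak_at_200(self):
        p = np.zeros((1, 512))
        p[0, 200] = 1.0
        out = segment_boundary(_series_with_profiles(p), threshold=0.5)
        assert out.r[0] == pytest.approx(200 * 4.5e-3)  # 0.9 mm

    def test_all_zero_invalid(self):
        out = segment_boundary(_series_with_profiles(np.zeros((1, 512))))
        assert not out.valid[0]

    def test_first_peak_rule(self):
        p = np.zeros((1, 512))
        p[0, 150] = 0.8
        p[0, 300] = 1.0
        out = segment_boundary(_series_with_profiles(p), threshold=0.5)
        assert out.r[0] == pytest.approx(150 * 4.5e-3)

    def test_dead_zone_skips_early_peak(self):
        p = np.zeros((1, 512))
        p[0, 3] = 1.0
        p[0, 100] = 1.0
        out = segment_boundary(_series_with_profiles(p), dead_zone=10)
        assert out.r[0] == pytest.approx(100 * 4.5e-3)

    def test_roundtrip_within_one_pixel(self, phantom, consts):
        profile = make_profile("custom", segments=[(-1.25, 5.0)],
                               start_x=15.0)
        short = make_profile("custom",
                             segments=[(-1.25, 0.03)], start_x=14.0)
        a = simulate_ascans(phantom, short, consts, emit_profiles=True)
        seg = segment_boundary(a, threshold=0.5)
        assert seg.valid.all()
        assert np.all(np.abs(seg.r - a.r) <= consts.pixel_spacing_mm)


# ---------------------------------------------------------------------------
# property: acquisition constants
# ---------------------------------------------------------------------------

def test_acquisition_constants_consistency():
    c = AcquisitionConstants()
    assert abs(c.f_mpi_raw - 1000.0 / c.imaging_period_ms) < 0.01
    with pytest.raises(ValueError):
        AcquisitionConstants(imaging_period_ms=30.0)
    with pytest.raises(ValueError):
        AcquisitionConstants(block_avg_factor=0)


@settings(max_examples=25, deadline=None)
@given(start=st.floats(5.0, 40.0),
       v=st.floats(0.1, 3.0),
       d1=st.floats(0.5, 10.0), d2=st.floats(0.5, 10.0))
def test_profile_position_continuous_piecewise_linear(start, v, d1, d2):
    p = make_profile("custom", segments=[(-v, d1), (v, d2)], start_x=start)
    ts = np.linspace(0, p.duration, 501)
    xs = p.position_at(ts)
    assert abs(xs[0] - start) < 1e-12
    assert abs(xs[-1] - (start - d1 + d2)) < 1e-9
    # continuity: bounded increments
    assert np.all(np.abs(np.diff(xs)) <= v * (ts[1] - ts[0]) + 1e-9)
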