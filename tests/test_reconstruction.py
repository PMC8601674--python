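"""Gridding reconstruction, density compensation, and motion rejection."""

import numpy as np
import pytest

from lungwater.acquisition import (
    golden_angle_trajectory,
    sample_kspace,
    trajectory_for_grid,
)
from lungwater.phantom import MotionModel, make_thorax
from lungwater.quantitation import lung_roi_from_slice
from lungwater.reconstruction import (
    ReconConfig,
    density_compensation,
    grid_reconstruct,
    pipe_menon_weights,
    reconstruct_pd,
    spoke_consistency_filter,
)
from lungwater.signal import SequenceParams, TissueParams, spgr_signal
from lungwater.validation import (
    conjugate_phase_reconstruct,
    dft_least_squares_reconstruct,
)

from conftest import make_disk_slice


class TestDensityCompensation:
    def test_ramp_weights_proportional_to_radius(self):
        traj = golden_angle_trajectory(8, samples_per_spoke=17, k_max=0.25)
        w = density_compensation(traj, "ramp")
        r = traj.radii[1:]
        assert np.allclose(w[0, 1:] / r, w[0, 1] / r[0])
        assert w[0, 0] > 0  # finite center weight

    def test_total_weight_close_to_sampled_area(self):
        traj = golden_angle_trajectory(64, samples_per_spoke=33, k_max=0.25)
        w = density_compensation(traj, "ramp")
        assert w.sum() == pytest.approx(np.pi * 0.25**2, rel=0.05)

    def test_pipe_menon_uniform_cartesian_constant_weights(self):
        g = (np.arange(16) - 8) * 0.01
        kx, ky = np.meshgrid(g, g, indexing="xy")
        w = pipe_menon_weights(kx.ravel(), ky.ravel(), 0.01)
        interior = w.reshape(16, 16)[2:-2, 2:-2]
        assert interior.std() / interior.mean() < 0.05

    def test_degenerate_trajectory_rejected(self):
        traj = golden_angle_trajectory(8, samples_per_spoke=17, k_max=0.25)
        traj.k_max = 0.0
        with pytest.raises(ValueError):
            density_compensation(traj, "ramp")

    def test_unknown_mode_rejected(self):
        traj = golden_angle_trajectory(8, samples_per_spoke=17, k_max=0.25)
        with pytest.raises(ValueError):
            density_compensation(traj, "voronoi")


class TestGridReconstruct:
    def test_disk_interior_within_5pct_of_analytic(self, seq):
        sl = make_disk_slice(n=64, radius_mm=60.0)
        traj = trajectory_for_grid(200, 64, sl.fov_mm)
        ks = sample_kspace(sl, seq, traj)
        img = grid_reconstruct(ks, ReconConfig(grid_size_px=64)).image
        sig = spgr_signal(seq, sl.tissue_table[1], 0)
        ax = (np.arange(64) - 32) * sl.pixel_size_mm
        x, y = np.meshgrid(ax, ax, indexing="xy")
        interior = img[np.hypot(x, y) < 40.0]
        assert interior.mean() == pytest.approx(sig, rel=0.05)

    def test_zero_kspace_gives_zero_image(self, seq, disk_slice):
        traj = trajectory_for_grid(16, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq, traj)
        ks.data[:] = 0
        img = grid_reconstruct(ks, ReconConfig(grid_size_px=32)).image
        assert np.allclose(img, 0.0)

    def test_bitwise_deterministic(self, seq, disk_slice):
        traj = trajectory_for_grid(16, 32, disk_slice.fov_mm)
        cfg = ReconConfig(grid_size_px=32)
        a = grid_reconstruct(sample_kspace(disk_slice, seq, traj), cfg).image
        b = grid_reconstruct(sample_kspace(disk_slice, seq, traj), cfg).image
        assert np.array_equal(a, b)

    def test_matches_conjugate_phase_oracle(self, seq, disk_slice):
        traj = trajectory_for_grid(64, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq, traj)
        img = grid_reconstruct(ks, ReconConfig(grid_size_px=32)).image
        oracle = conjugate_phase_reconstruct(ks, 32)
        nrmsd = np.sqrt(np.mean((img - oracle) ** 2)) / (oracle.max() - oracle.min())
        assert nrmsd <= 0.05

    def test_matches_least_squares_oracle(self, seq, disk_slice):
        traj = trajectory_for_grid(64, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq, traj)
        img = grid_reconstruct(ks, ReconConfig(grid_size_px=32)).image
        oracle = dft_least_squares_reconstruct(ks, 32)
        nrmsd = np.sqrt(np.mean((img - oracle) ** 2)) / (oracle.max() - oracle.min())
        assert nrmsd <= 0.05

    def test_chain_linearity_in_proton_density(self, seq):
        a = make_disk_slice(value_tissue=TissueParams(0.3, 900.0, 30.0))
        b = make_disk_slice(value_tissue=TissueParams(0.6, 900.0, 30.0))
        traj = trajectory_for_grid(64, 32, a.fov_mm)
        cfg = ReconConfig(grid_size_px=32)
        ia = grid_reconstruct(sample_kspace(a, seq, traj), cfg).image
        ib = grid_reconstruct(sample_kspace(b, seq, traj), cfg).image
        mask = ia > 0.1 * ia.max()
        assert np.allclose(ib[mask] / ia[mask], 2.0, rtol=0.01)


class TestSpokeConsistencyFilter:
    def test_static_noise_free_rejects_nothing(self, seq, disk_slice):
        traj = trajectory_for_grid(32, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq, traj)
        w, frac = spoke_consistency_filter(ks)
        assert frac == 0.0
        assert np.all(w == 1)

    def test_jitter_rejected_fraction_near_burst_probability(self, seq):
        sl = make_thorax(0.2, seed=1)
        traj = trajectory_for_grid(200, 64, sl.fov_mm)
        mot = MotionModel(jitter_amplitude_mm=8.0, jitter_burst_probability=0.2,
                          seed=5)
        ks = sample_kspace(sl, seq, traj, motion=mot)
        _, frac = spoke_consistency_filter(ks)
        assert 0.1 <= frac <= 0.3

    def test_infinite_threshold_keeps_everything(self, seq):
        sl = make_thorax(0.2, seed=1)
        traj = trajectory_for_grid(64, 32, sl.fov_mm)
        mot = MotionModel(jitter_amplitude_mm=8.0, jitter_burst_probability=0.3,
                          seed=2)
        ks = sample_kspace(sl, seq, traj, motion=mot)
        w, frac = spoke_consistency_filter(ks, threshold=np.inf)
        assert frac == 0.0
        cfg = ReconConfig(grid_size_px=32)
        assert np.array_equal(
            grid_reconstruct(ks, cfg, spoke_weights=w).image,
            grid_reconstruct(ks, cfg).image,
        )

    def test_too_few_spokes_rejected(self, seq, disk_slice):
        traj = trajectory_for_grid(4, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq, traj)
        with pytest.raises(ValueError):
            spoke_consistency_filter(ks)


class TestReconstructPd:
    def test_single_echo_first_echo_equals_grid_reconstruct(self, disk_slice):
        seq1 = SequenceParams(echo_times_ms=(0.1,))
        traj = trajectory_for_grid(32, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq1, traj)
        cfg = ReconConfig(grid_size_px=32)
        assert np.array_equal(
            reconstruct_pd(ks, cfg).image, grid_reconstruct(ks, cfg).image
        )

    def test_te0_extrapolation_recovers_decay_free_value(self, seq, disk_slice):
        # impose a known mono-exponential decay on every sample
        traj = trajectory_for_grid(64, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq, traj)
        t2star = 5.0
        base = ks.data[:, :, 0] / np.exp(-seq.echo_times_ms[0] / t2star)
        for e, te in enumerate(seq.echo_times_ms):
            ks.data[:, :, e] = base * np.exp(-te / t2star)
        cfg = ReconConfig(grid_size_px=32, echo_combine="te0_extrapolation")
        out = reconstruct_pd(ks, cfg)
        ref = grid_reconstruct(ks, ReconConfig(grid_size_px=32)).image
        expected = ref / np.exp(-seq.echo_times_ms[0] / t2star)
        mask = ref > 0.3 * ref.max()
        assert np.allclose(out.image[mask], expected[mask], rtol=0.02)

    def test_identical_echoes_return_first_echo_image(self, seq, disk_slice):
        traj = trajectory_for_grid(32, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq, traj)
        ks.data[:, :, 1] = ks.data[:, :, 0]
        ks.data[:, :, 2] = ks.data[:, :, 0]
        cfg = ReconConfig(grid_size_px=32, echo_combine="te0_extrapolation")
        out = reconstruct_pd(ks, cfg)
        first = grid_reconstruct(ks, ReconConfig(grid_size_px=32)).image
        mask = first > 1e-6 * first.max()
        assert np.allclose(out.image[mask], first[mask], rtol=1e-6)

    def test_te0_with_single_echo_rejected(self, disk_slice):
        seq1 = SequenceParams(echo_times_ms=(0.1,))
        traj = trajectory_for_grid(16, 32, disk_slice.fov_mm)
        ks = sample_kspace(disk_slice, seq1, traj)
        with pytest.raises(ValueError):
            reconstruct_pd(
                ks, ReconConfig(grid_size_px=32, echo_combine="te0_extrapolation")
            )


class TestMotionArtifactSuppression:
    def test_filter_lowers_lung_artifact_power_across_seeds(self, seq):
        sl = make_thorax(0.2, seed=1)
        n = 64
        traj = trajectory_for_grid(200, n, sl.fov_mm)
        cfg_off = ReconConfig(grid_size_px=n)
        cfg_on = ReconConfig(grid_size_px=n, motion_filter_enabled=True)
        static = reconstruct_pd(sample_kspace(sl, seq, traj), cfg_off).image
        roi = lung_roi_from_slice(sl, n)
        for seed in range(10):
            mot = MotionModel(jitter_amplitude_mm=8.0,
                              jitter_burst_probability=0.2, seed=seed)
            ks = sample_kspace(sl, seq, traj, motion=mot, noise_sigma=0.5,
                               seed=seed)
            p_off = np.mean(
                (reconstruct_pd(ks, cfg_off).image - static)[roi.mask] ** 2
            )
            p_on = np.mean(
                (reconstruct_pd(ks, cfg_on).image - static)[roi.mask] ** 2
            )
            assert p_on < p_off
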