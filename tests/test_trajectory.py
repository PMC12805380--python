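"""VD-CASPR sampling, navigator registration, phase correction, binning."""

import numpy as np
import pytest

from supermoco.motion import warp_image
from supermoco.operators import bin_kspace, zero_filled_recon
from supermoco.phantom import PhantomSpec, generate_phantom, simulate_acquisition
from supermoco.trajectory import (RespiratorySignal, apply_translational_correction,
                                  compute_acceleration_factors, elliptical_shutter,
                                  estimate_inav_translations, generate_vdcaspr,
                                  soft_gated_binning)
from supermoco.utils import fftc, ifftc


class TestVDCASPR:
    def test_full_sampling_covers_shutter(self):
        traj = generate_vdcaspr((16, 16), 1.0, 8, 300, seed=0)
        assert len(traj.unique_points()) == int(elliptical_shutter((16, 16)).sum())

    def test_requested_undersampling_achieved(self):
        traj = generate_vdcaspr((48, 48), 4.5, 60, 10, seed=2)
        assert abs(traj.achieved_undersampling() - 4.5) / 4.5 < 0.10

    def test_deterministic(self):
        a = generate_vdcaspr((24, 24), 2.0, 20, 12, seed=11)
        b = generate_vdcaspr((24, 24), 2.0, 20, 12, seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(a.readouts, b.readouts))

    def test_all_points_inside_shutter(self):
        traj = generate_vdcaspr((20, 28), 3.0, 16, 15, seed=4)
        shutter = elliptical_shutter((20, 28))
        for r in traj.readouts:
            assert shutter[r[:, 0], r[:, 1]].all()

    def test_density_decreases_with_radius(self):
        from supermoco.resample import measure_density_profile

        traj = generate_vdcaspr((64, 64), 6.0, 40, 20, seed=3)
        mask = np.zeros((64, 64), dtype=bool)
        u = traj.unique_points()
        mask[u[:, 0], u[:, 1]] = True
        prof = measure_density_profile(mask, n_annuli=5).densities
        assert prof[0] > prof[-1]

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_vdcaspr((2, 2), 1.0, 4, 4, seed=0)

    def test_golden_angle_rotation_between_heartbeats(self):
        # consecutive heartbeats acquire different interleaves when
        # several arms exist
        traj = generate_vdcaspr((32, 32), 2.0, 12, 40, seed=1)
        assert not np.array_equal(traj.readouts[0], traj.readouts[1])


class TestINavRegistration:
    def _navs(self, shifts, shape=(48, 48), seed=0):
        rng = np.random.default_rng(seed)
        from scipy import ndimage

        base = ndimage.gaussian_filter(rng.standard_normal(shape), 4.0)
        base -= base.min()
        navs = []
        ky = np.fft.fftfreq(shape[0])[:, None]
        kx = np.fft.fftfreq(shape[1])[None, :]
        for dy, dx in shifts:
            f = np.fft.fft2(base) * np.exp(-2j * np.pi * (ky * dy + kx * dx))
            navs.append(np.real(np.fft.ifft2(f)))
        return np.stack(navs)

    def test_identical_frames_zero_shift(self):
        navs = np.stack([self._navs([(0, 0)])[0]] * 5)
        sig = estimate_inav_translations(navs)
        assert np.abs(sig.fh).max() == 0 and np.abs(sig.lr).max() == 0

    def test_integer_shift_recovered(self):
        navs = self._navs([(0, 0), (-2.0, 3.0)])
        sig = estimate_inav_translations(navs)
        assert abs(sig.fh[1] - 3.0) < 0.2 and abs(sig.lr[1] - (-2.0)) < 0.2

    def test_subpixel_shift_recovered(self):
        navs = self._navs([(0, 0), (0.0, 1.5)])
        sig = estimate_inav_translations(navs)
        assert abs(sig.fh[1] - 1.5) < 0.25

    def test_flat_template_rejected(self):
        navs = np.zeros((3, 16, 16))
        with pytest.raises(ValueError):
            estimate_inav_translations(navs)


class TestTranslationalCorrection:
    def _static_raw(self):
        spec = PhantomSpec(grid_shape=(8, 16, 16), n_coils=1, n_bins=1, n_heartbeats=4,
                           motion_amplitude_vox=0.0, seed=3)
        truth = generate_phantom(spec)
        traj = generate_vdcaspr((16, 16), 1.0, 4, 300, seed=0)
        raw, _ = simulate_acquisition(truth, traj)
        return truth, raw

    def test_zero_shift_bit_exact(self):
        _, raw = self._static_raw()
        sig = RespiratorySignal(np.zeros(4), np.zeros(4))
        out = apply_translational_correction(raw, sig)
        assert all(np.array_equal(a, b) for a, b in zip(out.kspace, raw.kspace))

    def test_magnitudes_preserved(self):
        _, raw = self._static_raw()
        sig = RespiratorySignal(np.array([1.3, -0.4, 2.0, 0.0]),
                                np.array([0.2, 1.1, -0.7, 0.5]))
        out = apply_translational_correction(raw, sig)
        for a, b in zip(out.kspace, raw.kspace):
            assert np.abs(np.abs(a) - np.abs(b)).max() < 1e-12

    def test_inverse_correction_roundtrip(self):
        _, raw = self._static_raw()
        sig = RespiratorySignal(np.array([1.3, -0.4, 2.0, 0.7]),
                                np.array([0.2, 1.1, -0.7, 0.5]))
        neg = RespiratorySignal(-sig.fh, -sig.lr)
        out = apply_translational_correction(apply_translational_correction(raw, sig), neg)
        for a, b in zip(out.kspace, raw.kspace):
            assert np.abs(a - b).max() < 1e-12

    def test_integer_shift_image_oracle(self):
        """Correcting an integer in-plane shift equals circularly shifting
        the reconstructed image (periodic boundaries)."""
        truth, raw = self._static_raw()
        shift = (2, -3)  # (x, y) integer voxels
        sig = RespiratorySignal(np.full(4, float(shift[0])), np.full(4, float(shift[1])))
        corrected = apply_translational_correction(raw, sig)
        plan = soft_gated_binning(corrected.trajectory(), sig, 1, hr_grid_yz=(16, 16))
        img_corr = zero_filled_recon(bin_kspace(corrected, plan), plan, truth.coil_maps)[0]
        plan0 = soft_gated_binning(raw.trajectory(), sig, 1, hr_grid_yz=(16, 16))
        img_raw = zero_filled_recon(bin_kspace(raw, plan0), plan0, truth.coil_maps)[0]
        rolled = np.roll(img_raw, (-shift[0], -shift[1]), axis=(0, 1))
        assert np.abs(img_corr - rolled).max() < 1e-10

    def test_heartbeat_mismatch_rejected(self):
        _, raw = self._static_raw()
        with pytest.raises(ValueError):
            apply_translational_correction(raw, RespiratorySignal(np.zeros(7), np.zeros(7)))


class TestSoftGatedBinning:
    def _traj(self, nh):
        return generate_vdcaspr((16, 16), 2.0, nh, 20, seed=0)

    def test_equal_populations_100_heartbeats(self):
        traj = self._traj(100)
        sig = RespiratorySignal(np.linspace(0, 5, 100), np.zeros(100))
        plan = soft_gated_binning(traj, sig, 4)
        counts = np.bincount(plan.hard_assignment, minlength=4)
        assert list(counts) == [25, 25, 25, 25]

    def test_populations_differ_by_at_most_one(self):
        traj = self._traj(23)
        sig = RespiratorySignal(np.random.default_rng(0).normal(size=23), np.zeros(23))
        plan = soft_gated_binning(traj, sig, 4)
        counts = np.bincount(plan.hard_assignment, minlength=4)
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 23

    def test_constant_signal_weight_one(self):
        traj = self._traj(8)
        sig = RespiratorySignal(np.zeros(8), np.zeros(8))
        plan = soft_gated_binning(traj, sig, 2)
        for acq in plan.bins:
            assert np.all(acq.weights == 1.0)

    def test_weights_in_unit_interval_and_sharing(self):
        traj = self._traj(40)
        sig = RespiratorySignal(np.linspace(0, 4, 40), np.zeros(40))
        plan = soft_gated_binning(traj, sig, 4)
        shared = 0
        for acq in plan.bins:
            assert np.all((acq.weights >= 0) & (acq.weights <= 1))
            hbs = {h for members in acq.sources for h, _, _ in members}
            shared += len(hbs)
        # soft gating shares heartbeats between bins on a ramp signal
        assert shared > 40

    def test_reference_bin_is_end_expiration(self):
        traj = self._traj(12)
        fh = np.array([5, 4, 4.5, 0.1, 0.2, 0.05, 2, 2.2, 2.4, 5.1, 0.3, 2.1])
        plan = soft_gated_binning(traj, RespiratorySignal(fh, np.zeros(12)), 4)
        means = [fh[plan.hard_assignment == j].mean() for j in range(4)]
        assert plan.reference_bin == int(np.argmin(means))

    def test_too_many_bins_rejected(self):
        traj = self._traj(3)
        with pytest.raises(ValueError):
            soft_gated_binning(traj, RespiratorySignal(np.zeros(3), np.zeros(3)), 5)


class TestAcceleration:
    def test_printed_factor_product(self):
        # accounting identity at the printed precision: 1.15 x 16.33 -> 18.8
        assert round(1.15 * 16.33, 1) == 18.8

    def test_full_sampling_is_unity(self):
        traj = generate_vdcaspr((16, 16), 1.0, 8, 300, seed=0)
        sig = RespiratorySignal(np.zeros(8), np.zeros(8))
        plan = soft_gated_binning(traj, sig, 2)
        v, s, o = compute_acceleration_factors(plan)
        assert (v, s, o) == (1.0, 1.0, 1.0)

    def test_two_by_two_with_undersampling_near_18(self):
        # 2x2 SR with 4.5-fold undersampling: overall within 10% of 18
        traj = generate_vdcaspr((32, 16), 4.5, 48, 5, seed=2)
        sig = RespiratorySignal(np.linspace(0, 3, 48), np.zeros(48))
        plan = soft_gated_binning(traj, sig, 4, hr_grid_yz=(64, 32))
        v, s, o = compute_acceleration_factors(plan)
        counted = (elliptical_shutter((64, 32)).sum() / len(plan.unique_points()))
        assert abs(o - counted) / counted < 1e-12  # exact integer accounting
        assert abs(o - 18.0) / 18.0 < 0.10

    def test_empty_plan_rejected(self, small_problem):
        _, _, plan = small_problem
        import copy

        empty = copy.deepcopy(plan)
        for acq in empty.bins:
            acq.readouts = acq.readouts[:0]
            acq.weights = acq.weights[:0]
            acq.sources = []
        with pytest.raises(ValueError):
            compute_acceleration_factors(empty)
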