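"""x-direction patching round trips; annulus densities; down-sampling; padding."""

import numpy as np
import pytest

from supermoco.patching import PatchPlan, patch_starts, recombine_patches, retained_interval, split_into_patches
from supermoco.phantom import PhantomSpec, generate_phantom, simulate_acquisition
from supermoco.resample import (AnnulusDensityProfile, measure_density_profile,
                                pad_kspace_to_multiple16, retrospective_downsample)
from supermoco.trajectory import elliptical_shutter, generate_vdcaspr, soft_gated_binning
from supermoco.utils import next_multiple


class TestPatchPlan:
    def test_printed_geometry(self):
        plan = PatchPlan(thickness=32, discard=5, overlap=4)
        assert plan.retained == 22 and plan.stride == 18

    def test_thickness_must_be_multiple_of_16(self):
        with pytest.raises(ValueError):
            PatchPlan(thickness=20)

    def test_single_patch_when_exact(self):
        plan = PatchPlan()
        starts = patch_starts(32, plan)
        assert starts == [0]
        lo, hi = retained_interval(0, 32, plan, 0, 1)
        assert (lo, hi) == (0, 32)

    def test_too_thin_volume_rejected(self):
        with pytest.raises(ValueError):
            patch_starts(20, PatchPlan())


class TestPatchingRoundTrip:
    @pytest.mark.parametrize("x_dim", list(range(32, 129)))
    def test_roundtrip_exact_all_sizes(self, x_dim):
        """Identity processing recombines exactly for every x-dim 32..128."""
        rng = np.random.default_rng(x_dim)
        vol = rng.standard_normal((x_dim, 3, 4)) + 1j * rng.standard_normal((x_dim, 3, 4))
        plan = PatchPlan(thickness=32, discard=5, overlap=4)
        patches, starts = split_into_patches(vol, plan)
        out = recombine_patches(patches, starts, x_dim, plan)
        assert np.array_equal(out, vol)

    def test_coverage_and_interior_overlap_x100(self):
        plan = PatchPlan()
        x_dim = 100
        starts = patch_starts(x_dim, plan)
        n = len(starts)
        covered = np.zeros(x_dim, dtype=int)
        intervals = [retained_interval(s, x_dim, plan, i, n) for i, s in enumerate(starts)]
        for lo, hi in intervals:
            covered[lo:hi] += 1
        assert (covered > 0).all()
        assert covered.max() <= 2  # pairwise overlaps only
        # brute-force overlap widths between adjacent retained intervals
        overlaps = [intervals[i][1] - intervals[i + 1][0] for i in range(n - 1)]
        assert all(o >= 1 for o in overlaps)
        assert all(o == plan.overlap for o in overlaps[:-1])  # stride-regular pairs

    def test_overlap_regions_are_means(self):
        rng = np.random.default_rng(0)
        x_dim = 64
        plan = PatchPlan()
        vol = rng.standard_normal((x_dim, 2, 2))
        patches, starts = split_into_patches(vol, plan)
        # perturb each patch differently so overlaps actually differ
        patches = [p + i for i, p in enumerate(patches)]
        out = recombine_patches(patches, starts, x_dim, plan)
        # direct per-voxel accumulation oracle
        acc = np.zeros((x_dim, 2, 2))
        cnt = np.zeros(x_dim)
        n = len(starts)
        for i, (p, s) in enumerate(zip(patches, starts)):
            lo, hi = retained_interval(s, x_dim, plan, i, n)
            acc[lo:hi] += p[lo - s:hi - s]
            cnt[lo:hi] += 1
        assert np.allclose(out, acc / cnt[:, None, None], atol=1e-12)
        assert (cnt > 0).all()


class TestDensityProfile:
    def test_full_shutter_all_ones(self):
        mask = elliptical_shutter((40, 40))
        prof = measure_density_profile(mask)
        assert prof.n_annuli == 20 and len(prof.densities) == 20
        assert np.allclose(prof.densities, 1.0)

    def test_checkerboard_half_density(self):
        grid = (64, 64)
        mask = np.indices(grid).sum(axis=0) % 2 == 0
        mask &= elliptical_shutter(grid)
        prof = measure_density_profile(mask)
        # exhaustive counting oracle: recount every annulus point by point
        ny, nz = grid
        shutter = elliptical_shutter(grid)
        expected = np.zeros(20)
        for j in range(20):
            hits = total = 0
            for y in range(ny):
                for z in range(nz):
                    if not shutter[y, z]:
                        continue
                    r = np.hypot((y - ny // 2) / (ny / 2), (z - nz // 2) / (nz / 2))
                    if min(int(r * 20), 19) == j:
                        total += 1
                        hits += int(mask[y, z])
            expected[j] = hits / total
        assert np.allclose(prof.densities, expected, atol=1e-12)
        # half-sampling overall: mean density near one half
        assert abs(prof.densities.mean() - 0.5) < 0.05

    def test_empty_shutter_rejected(self):
        with pytest.raises(ValueError):
            measure_density_profile(np.zeros((0, 0), dtype=bool))


@pytest.fixture(scope="module")
def hr_raw():
    spec = PhantomSpec(grid_shape=(8, 32, 32), n_coils=2, n_bins=2, n_heartbeats=16,
                       motion_amplitude_vox=1.0, seed=9)
    truth = generate_phantom(spec)
    traj = generate_vdcaspr((32, 32), 1.2, 16, 50, seed=2)
    raw, _ = simulate_acquisition(truth, traj)
    return raw


class TestRetrospectiveDownsample:
    def _target(self, sr=2, under=2.0, seed=5):
        lr_traj = generate_vdcaspr((16, 16), under, 16, 10, seed=seed)
        mask = np.zeros((16, 16), dtype=bool)
        u = lr_traj.unique_points()
        mask[u[:, 0], u[:, 1]] = True
        return measure_density_profile(mask)

    def test_identity_when_target_full(self, hr_raw):
        prof = AnnulusDensityProfile(np.ones(20))
        out, rep = retrospective_downsample(hr_raw, 1, prof, seed=0)
        src = {tuple(p) for t in hr_raw.traj_lines for p in t}
        kept = {tuple(p) for t in out.traj_lines for p in t}
        # all acquired lines inside the (unscaled) shutter are retained
        assert kept == {p for p in src
                        if ((p[0] - 16) / 16.0) ** 2 + ((p[1] - 16) / 16.0) ** 2 <= 1.0}

    def test_retained_subset_and_bit_exact(self, hr_raw):
        out, rep = retrospective_downsample(hr_raw, 2, self._target(), seed=1)
        for h in range(out.n_heartbeats):
            src_pts = {tuple(p): i for i, p in enumerate(hr_raw.traj_lines[h])}
            for i, p in enumerate(out.traj_lines[h]):
                hr_p = (p[0] + 8, p[1] + 8)  # undo re-centering offset
                assert hr_p in src_pts  # subset: never synthesized
                j = src_pts[hr_p]
                assert np.array_equal(out.kspace[h][i], hr_raw.kspace[h][j])

    def test_density_match_within_tolerance(self, hr_raw):
        target = self._target()
        out, rep = retrospective_downsample(hr_raw, 2, target, seed=3)
        mask = np.zeros((16, 16), dtype=bool)
        pts = np.concatenate([t for t in out.traj_lines if t.size])
        mask[pts[:, 0], pts[:, 1]] = True
        achieved = measure_density_profile(mask).densities
        shutter_r = elliptical_shutter((16, 16))
        counts = np.zeros(20)
        from supermoco.resample import _annulus_of, _norm_radius

        yy, zz = np.nonzero(shutter_r)
        ann = _annulus_of(np.clip(_norm_radius(yy, zz, (16, 16)), 0, 1), 20)
        for j in range(20):
            counts[j] = max((ann == j).sum(), 1)
        # within max(5%, one line) per annulus, except recorded shortfalls
        for j in range(20):
            if rep.shortfall[j] > 0:
                continue
            tol = max(0.05, 1.0 / counts[j])
            assert abs(achieved[j] - target.densities[j]) <= tol + 1e-12

    def test_deterministic(self, hr_raw):
        a, _ = retrospective_downsample(hr_raw, 2, self._target(), seed=11)
        b, _ = retrospective_downsample(hr_raw, 2, self._target(), seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(a.traj_lines, b.traj_lines))


class TestPadKspace:
    @pytest.mark.parametrize("dim,expected", [(128, 128), (129, 144), (16, 16), (17, 32)])
    def test_next_multiple(self, dim, expected):
        assert next_multiple(dim) == expected

    def test_padding_preserves_image_on_original_grid(self):
        """Evaluating the padded-grid reconstruction at the original voxel
        positions (explicit non-uniform DFT) reproduces the original image."""
        rng = np.random.default_rng(2)
        ny = nz = 12  # pads to 16
        spec = PhantomSpec(grid_shape=(8, ny, nz), n_coils=1, n_bins=1, n_heartbeats=4,
                           motion_amplitude_vox=0.0, seed=4)
        truth = generate_phantom(spec)
        traj = generate_vdcaspr((ny, nz), 1.0, 4, 200, seed=1)
        raw, _ = simulate_acquisition(truth, traj)
        plan = soft_gated_binning(raw.trajectory(), truth.breathing_signal, 1,
                                  hr_grid_yz=(ny, nz))
        from supermoco.operators import bin_kspace, zero_filled_recon

        b = bin_kspace(raw, plan)
        img = zero_filled_recon(b, plan, truth.coil_maps)[0]
        b2, plan2 = pad_kspace_to_multiple16(b, plan)
        assert plan2.grid_yz == (16, 16)
        maps2 = np.ones((1, 8, 16, 16), dtype=complex)
        img2 = zero_filled_recon(b2, plan2, maps2)[0]
        # oracle: evaluate the padded trig polynomial at original positions
        from supermoco.utils import centered_freqs, fftc

        k2 = fftc(img2, axes=(1, 2))
        eval_mat_y = np.exp(2j * np.pi * np.outer((np.arange(ny) - ny // 2) / ny,
                                                  centered_freqs(16))) / np.sqrt(16)
        eval_mat_z = np.exp(2j * np.pi * np.outer((np.arange(nz) - nz // 2) / nz,
                                                  centered_freqs(16))) / np.sqrt(16)
        resampled = np.einsum("ya,xab,zb->xyz", eval_mat_y, k2, eval_mat_z)
        assert np.abs(resampled - img) .max() <= 1e-10

    def test_unchanged_when_already_multiple(self, static_truth):
        traj = generate_vdcaspr((16, 16), 1.5, 8, 40, seed=0)
        raw, _ = simulate_acquisition(static_truth, traj)
        plan = soft_gated_binning(raw.trajectory(), static_truth.breathing_signal, 2,
                                  hr_grid_yz=(16, 16))
        from supermoco.operators import bin_kspace

        b = bin_kspace(raw, plan)
        b2, plan2 = pad_kspace_to_multiple16(b, plan)
        assert plan2.grid_yz == plan.grid_yz
        assert all(np.array_equal(x, y) for x, y in zip(b.data, b2.data))
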