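"""Encoding operator: adjointness, dense oracles, CG and SENSE solvers."""

import numpy as np
import pytest

from conftest import dense_matrix
from supermoco.motion import MotionFieldSet
from supermoco.operators import (BinnedKSpace, EncodingOperator, bin_kspace,
                                 cg_solve_step1, conjugate_gradient, iterative_sense,
                                 zero_filled_recon)
from supermoco.phantom import PhantomSpec, generate_phantom, simulate_acquisition
from supermoco.trajectory import generate_vdcaspr, soft_gated_binning
from supermoco.utils import ifftc, real_dot


def random_b_like(b, rng):
    return BinnedKSpace([rng.standard_normal(d.shape) + 1j * rng.standard_normal(d.shape)
                         for d in b.data], b.hybrid)


@pytest.fixture(scope="module")
def operator(small_problem):
    truth, raw, plan = small_problem
    return EncodingOperator(plan, truth.coil_maps, truth.true_fields), raw, truth, plan


class TestAdjointness:
    def test_composed_operator_adjoint(self, operator, rng):
        E, raw, truth, plan = operator
        rho = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        b = random_b_like(E.forward(rho), rng)
        lhs = sum(real_dot(x, y) for x, y in zip(E.forward(rho).data, b.data))
        rhs = real_dot(rho, E.adjoint(b))
        assert abs(lhs - rhs) <= 1e-6 * max(abs(lhs), 1.0)

    @pytest.mark.parametrize("factor", ["W", "D", "F", "C", "M"])
    def test_each_factor_adjoint(self, operator, rng, factor):
        """Randomized inner-product adjoint test for every factor of E."""
        E, raw, truth, plan = operator
        if factor == "M":
            x = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
            y = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
            lhs = real_dot(truth.true_fields.warp(x, 1), y)
            rhs = real_dot(x, truth.true_fields.warp_adjoint(y, 1))
        elif factor == "C":
            x = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
            y = rng.standard_normal((2, 8, 8, 8)) + 1j * rng.standard_normal((2, 8, 8, 8))
            lhs = real_dot(truth.coil_maps * x[None], y)
            rhs = real_dot(x, np.sum(np.conj(truth.coil_maps) * y, axis=0))
        elif factor == "F":
            from supermoco.utils import fftc

            x = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
            y = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
            lhs = real_dot(fftc(x), y)
            rhs = real_dot(x, ifftc(y))
        else:  # W and D act jointly through gather/scatter
            from supermoco.operators import _gather, _scatter

            acq = plan.bins[0]
            k = rng.standard_normal((2, 8, 8, 8)) + 1j * rng.standard_normal((2, 8, 8, 8))
            s = rng.standard_normal((acq.n_samples, 2, 8)) + 1j * rng.standard_normal((acq.n_samples, 2, 8))
            lhs = real_dot(_gather(k, acq), s)
            rhs = real_dot(k, _scatter(s, acq, (8, 8)))
        assert abs(lhs - rhs) <= 1e-6 * max(abs(lhs), 1.0)

    def test_normal_operator_psd(self, operator, rng):
        E = operator[0]
        for _ in range(3):
            rho = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
            assert real_dot(rho, E.normal(rho)) >= 0

    def test_linearity(self, operator, rng):
        E = operator[0]
        x = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        y = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        fa = E.forward(2.0 * x + 3.0 * y)
        fx, fy = E.forward(x), E.forward(y)
        for a, bx, by in zip(fa.data, fx.data, fy.data):
            assert np.abs(a - 2.0 * bx - 3.0 * by).max() < 1e-10


def make_tiny_problem(n=4, n_bins=2, n_coils=2, seed=7):
    """Hand-built n^3 problem: random plan, coil maps and smooth motion."""
    from supermoco.motion import scaling_and_squaring
    from supermoco.phantom import simulate_coil_maps
    from supermoco.trajectory import BinAcquisition, SamplingPlan, elliptical_shutter

    r = np.random.default_rng(seed)
    pts = np.argwhere(elliptical_shutter((n, n)))
    bins = []
    for j in range(n_bins):
        sel = r.choice(len(pts), size=max(3, len(pts) * 2 // 3), replace=False)
        bins.append(BinAcquisition(readouts=pts[np.sort(sel)],
                                   weights=r.uniform(0.3, 1.0, size=len(sel)),
                                   sources=None))
    plan = SamplingPlan(n_bins=n_bins, bins=bins, grid_yz=(n, n), lr_grid_yz=(n, n))
    coil_maps = simulate_coil_maps((n, n, n), n_coils, seed=seed)
    fields = np.zeros((n_bins, 3, n, n, n))
    for j in range(1, n_bins):
        v = r.normal(0, 0.3, size=(3, n, n, n))
        fields[j] = scaling_and_squaring(v, 4)
    motion = MotionFieldSet(fields, reference=0)
    E = EncodingOperator(plan, coil_maps, motion)
    b = random_b_like(E.forward(np.zeros((n, n, n), dtype=complex)),
                      np.random.default_rng(seed + 1))
    return E, b, coil_maps, plan


class TestDenseOracle:
    """Direct dense solves on 4x4x4 problems as independent oracles."""

    def test_forward_matches_materialized_matrix(self, rng):
        E, b, maps, plan = make_tiny_problem()
        n = 64

        def flat_forward(x):
            return np.concatenate([d.ravel() for d in E.forward(x).data])

        A = dense_matrix(flat_forward, n, (4, 4, 4))
        x = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        assert np.abs(A @ x - flat_forward(x.reshape(4, 4, 4))).max() <= 1e-10

    def test_cg_matches_dense_solve(self, rng):
        E, b, maps, plan = make_tiny_problem()
        lam = 1.5
        g = rng.standard_normal((4, 4, 4)) + 1j * rng.standard_normal((4, 4, 4))
        x_cg = cg_solve_step1(E, b, g, lam, n_iter=100)
        A = dense_matrix(lambda v: E.normal(v) + lam * v, 64, (4, 4, 4))
        rhs = (E.adjoint(b) + lam * g).ravel()
        x_dense = np.linalg.solve(A, rhs)
        rel = np.linalg.norm(x_cg.ravel() - x_dense) / np.linalg.norm(x_dense)
        assert rel <= 1e-6

    def test_sense_matches_dense_solve(self, rng):
        E, b, maps, plan = make_tiny_problem()
        zf = zero_filled_recon(b, plan, maps)
        x = iterative_sense(zf[0], plan.bins[0], maps, n_iter=150)
        eps = 1e-6

        def apply_a(v):
            op = EncodingOperator(plan, maps, MotionFieldSet.identity(plan.n_bins, (4, 4, 4)))
            bb = op.forward(v)
            data = [d if j == 0 else np.zeros_like(d) for j, d in enumerate(bb.data)]
            return op.adjoint_bins(BinnedKSpace(data))[0] + eps * v

        A = dense_matrix(apply_a, 64, (4, 4, 4))
        x_dense = np.linalg.solve(A, zf[0].ravel())
        rel = np.linalg.norm(x.ravel() - x_dense) / np.linalg.norm(x_dense)
        assert rel <= 1e-6


class TestZeroFilled:
    def test_full_sampling_single_coil_is_inverse_dft(self, static_truth):
        traj = generate_vdcaspr((16, 16), 1.0, 8, 300, seed=0)
        raw, _ = simulate_acquisition(static_truth, traj)
        plan = soft_gated_binning(raw.trajectory(), static_truth.breathing_signal, 2,
                                  hr_grid_yz=(16, 16))
        b = bin_kspace(raw, plan)
        zf = zero_filled_recon(b, plan, static_truth.coil_maps)
        # shutter-band-limited reference: corners of k-space are never acquired
        from supermoco.trajectory import elliptical_shutter
        from supermoco.utils import fftc

        k = fftc(static_truth.reference_image)
        k *= elliptical_shutter((16, 16))[None]
        ref = ifftc(k)
        assert np.abs(zf[0] - ref).max() <= 1e-6 * np.abs(ref).max()

    def test_dc_only_bin_is_constant_per_slice(self, static_truth):
        # uniform single coil: a bin acquiring only the DC readout
        # reconstructs to a y-z-constant image per x-slice
        traj = generate_vdcaspr((16, 16), 1.0, 8, 300, seed=0)
        raw, _ = simulate_acquisition(static_truth, traj)
        plan = soft_gated_binning(raw.trajectory(), static_truth.breathing_signal, 1,
                                  hr_grid_yz=(16, 16))
        import copy

        p = copy.deepcopy(plan)
        for acq in p.bins:
            keep = (acq.readouts[:, 0] == 8) & (acq.readouts[:, 1] == 8)
            acq.readouts = acq.readouts[keep]
            acq.weights = acq.weights[keep]
            acq.sources = [s for s, k in zip(acq.sources, keep) if k]
        b = bin_kspace(raw, p)
        zf = zero_filled_recon(b, p, static_truth.coil_maps)
        for x in range(8):
            sl = zf[0][x]
            assert np.abs(sl - sl.mean()).max() <= 1e-10

    def test_linearity_in_weights(self, small_problem):
        truth, raw, plan = small_problem
        import copy

        b = bin_kspace(raw, plan)
        zf1 = zero_filled_recon(b, plan, truth.coil_maps)
        p2 = copy.deepcopy(plan)
        b2 = BinnedKSpace([d.copy() for d in b.data])
        for acq in p2.bins:
            acq.weights = 2.0 * acq.weights
        # doubling W^T doubles rho_ZF for fixed sample values
        zf2 = zero_filled_recon(b2, p2, truth.coil_maps)
        assert np.allclose(zf2, 2.0 * zf1, atol=1e-12)


class TestCG:
    def test_dominant_penalty_returns_prior(self, operator, rng):
        E, raw, truth, plan = operator
        g = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        zero_b = BinnedKSpace([np.zeros_like(d) for d in E.forward(g).data])
        x = cg_solve_step1(E, zero_b, g, lam=1e8, n_iter=10)
        assert np.linalg.norm(x - g) / np.linalg.norm(g) <= 1e-4

    def test_rhs_identity_adjoint_equals_warped_zero_filled(self, operator):
        """E*b == sum_i M_i* rho_ZF,i (the compositional identity that lets
        zero-filled images stand in for raw k-space)."""
        E, raw, truth, plan = operator
        b = bin_kspace(raw, plan)
        atb = E.adjoint(b)
        zf = zero_filled_recon(b, plan, truth.coil_maps)
        comp = sum(truth.true_fields.warp_adjoint(zf[j], j) for j in range(plan.n_bins))
        assert np.abs(atb - comp).max() <= 1e-10

    def test_lambda_validation(self, operator):
        E, raw, truth, plan = operator
        b = bin_kspace(raw, plan)
        with pytest.raises(ValueError):
            cg_solve_step1(E, b, np.zeros((8, 8, 8), dtype=complex), lam=0.0)

    def test_residual_monotone(self, operator, rng):
        E, raw, truth, plan = operator
        b = bin_kspace(raw, plan)
        g = np.zeros((8, 8, 8), dtype=complex)
        _, res = cg_solve_step1(E, b, g, lam=1.5, n_iter=20, return_residuals=True)
        assert np.all(np.diff(res) <= 1e-9 * res[0])


class TestIterativeSense:
    def test_fully_sampled_single_coil_recovers_image(self, static_truth):
        traj = generate_vdcaspr((16, 16), 1.0, 8, 300, seed=0)
        raw, _ = simulate_acquisition(static_truth, traj)
        plan = soft_gated_binning(raw.trajectory(), static_truth.breathing_signal, 1,
                                  hr_grid_yz=(16, 16))
        b = bin_kspace(raw, plan)
        zf = zero_filled_recon(b, plan, static_truth.coil_maps)
        x = iterative_sense(zf[0], plan.bins[0], static_truth.coil_maps, n_iter=5)
        # fully sampled single coil: the SENSE solution is the zero-filled
        # image itself (A ~ identity up to the Tikhonov term)
        assert np.abs(x - zf[0]).max() <= 1e-5 * np.abs(zf[0]).max()

    def test_default_iteration_count_is_ten(self):
        import inspect

        sig = inspect.signature(iterative_sense)
        assert sig.parameters["n_iter"].default == 10

    def test_invalid_iterations_rejected(self, small_problem):
        truth, raw, plan = small_problem
        b = bin_kspace(raw, plan)
        zf = zero_filled_recon(b, plan, truth.coil_maps)
        with pytest.raises(ValueError):
            iterative_sense(zf[0], plan.bins[0], truth.coil_maps, n_iter=0)
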