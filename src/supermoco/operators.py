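"""The multi-bin motion-compensated encoding operator and its solvers.

``E = W D F C M``: warp the reference-bin image into each respiratory
bin (M), multiply by coil sensitivities (C), take the centered unitary
3-D DFT (F), keep only acquired readouts — dropping both unacquired
center readouts and everything beyond the low-resolution shutter (D) —
and weight by the soft-gating weights (W).  Forward and adjoint are
exact numerical adjoints by construction.

Because the readout (x) direction is fully sampled, the operator can
also run in hybrid mode (``fft_x=False``) where samples live in
(x, ky, kz) space; this is what makes x-direction patching exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion import MotionFieldSet
from .trajectory import BinAcquisition, SamplingPlan
from .utils import fftc, ifftc

__all__ = [
    "BinnedKSpace",
    "EncodingOperator",
    "bin_kspace",
    "zero_filled_recon",
    "conjugate_gradient",
    "cg_solve_step1",
    "iterative_sense",
]


@dataclass
class BinnedKSpace:
    """Soft-gated multi-bin multi-coil sample vector ``b``.

    ``data[i]`` has shape (K_i, Nc, Nx).  ``hybrid`` marks whether the
    readout axis has already been inverse-transformed to image x.
    """

    data: list
    hybrid: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.data)

    def copy(self) -> "BinnedKSpace":
        return BinnedKSpace([d.copy() for d in self.data], self.hybrid)

    def to_hybrid(self) -> "BinnedKSpace":
        """Inverse-FFT every kx line to image x (unitary, centered)."""
        if self.hybrid:
            return self.copy()
        return BinnedKSpace([ifftc(d, axes=(2,)) for d in self.data], hybrid=True)


def bin_kspace(raw, plan: SamplingPlan) -> BinnedKSpace:
    """Assemble the soft-gated sample vector b = W * (measured samples).

    Repeated acquisitions of the same (ky, kz) line within a bin are
    combined into a weight-weighted average before the bin's soft-gating
    weight is applied once (the literal encoding model applies W to the
    sorted samples; averaging repeats is the standard multiple-averages
    treatment and keeps the zero-filled path exact under full sampling).
    """
    data = []
    for acq in plan.bins:
        rows = np.empty((acq.n_samples,) + raw.kspace[0].shape[1:], dtype=complex)
        for i, members in enumerate(acq.sources):
            num = 0.0
            den = 0.0
            for h, row, w in members:
                num = num + w * raw.kspace[h][row]
                den += w
            rows[i] = (num / den) * acq.weights[i]
        data.append(rows)
    return BinnedKSpace(data)


def _gather(kgrid: np.ndarray, acq: BinAcquisition) -> np.ndarray:
    """(Nc, Nx, Y, Z) grid -> (K, Nc, Nx) weighted samples."""
    s = kgrid[:, :, acq.readouts[:, 0], acq.readouts[:, 1]]  # (Nc, Nx, K)
    return np.moveaxis(s, 2, 0) * acq.weights[:, None, None]


def _scatter(samples: np.ndarray, acq: BinAcquisition, grid_yz) -> np.ndarray:
    """(K, Nc, Nx) weighted samples -> (Nc, Nx, Y, Z) grid (adjoint of gather)."""
    k, nc, nx = samples.shape
    out = np.zeros(grid_yz + (nc, nx), dtype=complex)
    np.add.at(out, (acq.readouts[:, 0], acq.readouts[:, 1]), samples * acq.weights[:, None, None])
    return np.moveaxis(out, (0, 1), (2, 3))


@dataclass
class EncodingOperator:
    """Matrix-free forward/adjoint pair for ``E = W D F C M``."""

    plan: SamplingPlan
    coil_maps: np.ndarray  # (Nc, X, Y, Z)
    motion: MotionFieldSet
    fft_x: bool = True

    def __post_init__(self):
        self.grid_shape = self.coil_maps.shape[1:]
        if self.grid_shape[1:] != tuple(self.plan.grid_yz):
            raise ValueError("coil map grid does not match sampling plan grid")
        if tuple(self.motion.grid_shape) != tuple(self.grid_shape):
            raise ValueError("motion field grid does not match image grid")
        if self.motion.n_bins != self.plan.n_bins:
            raise ValueError("motion field count does not match bin count")

    @property
    def fft_axes(self):
        return (1, 2, 3) if self.fft_x else (2, 3)

    def forward(self, rho: np.ndarray) -> BinnedKSpace:
        if rho.shape != tuple(self.grid_shape):
            raise ValueError(f"image shape {rho.shape} does not match grid {self.grid_shape}")
        data = []
        for j in range(self.plan.n_bins):
            xb = self.motion.warp(rho, j)
            k = fftc(self.coil_maps * xb[None], axes=self.fft_axes)
            data.append(_gather(k, self.plan.bins[j]))
        return BinnedKSpace(data, hybrid=not self.fft_x)

    def adjoint(self, b: BinnedKSpace) -> np.ndarray:
        imgs = self.adjoint_bins(b)
        out = np.zeros(self.grid_shape, dtype=complex)
        for j in range(self.plan.n_bins):
            out += self.motion.warp_adjoint(imgs[j], j)
        return out

    def adjoint_bins(self, b: BinnedKSpace) -> np.ndarray:
        """Per-bin coil-combined adjoint images (no motion): C* F^-1 D^T W^T b."""
        if b.n_bins != self.plan.n_bins:
            raise ValueError("sample vector does not match sampling plan")
        out = np.empty((self.plan.n_bins,) + tuple(self.grid_shape), dtype=complex)
        for j in range(self.plan.n_bins):
            k = _scatter(b.data[j], self.plan.bins[j], tuple(self.plan.grid_yz))
            img = ifftc(k, axes=self.fft_axes)
            out[j] = np.sum(np.conj(self.coil_maps) * img, axis=0)
        return out

    def _w2_masks(self):
        """Per-bin squared-soft-weight masks on the (Y, Z) grid.

        Since readout points are unique within a bin, the composition
        D^T W^T W D of the sampling operator collapses to a pointwise
        multiplication of the k-grid by the squared weights.
        """
        masks = getattr(self, "_w2_cache", None)
        if masks is None:
            masks = []
            for acq in self.plan.bins:
                m = np.zeros(tuple(self.plan.grid_yz))
                m[acq.readouts[:, 0], acq.readouts[:, 1]] = acq.weights**2
                masks.append(m)
            self._w2_cache = masks
        return masks

    def normal(self, rho: np.ndarray) -> np.ndarray:
        """``E* E rho`` with the sampling composition fused to a mask.

        The inner centering shifts of F and F^-1 cancel against an
        ifftshifted copy of the mask, halving the roll overhead.
        """
        from scipy import fft as _fft

        masks = self._w2_masks()
        shifted = getattr(self, "_w2_shifted", None)
        if shifted is None:
            shifted = [np.fft.ifftshift(m) for m in masks]
            self._w2_shifted = shifted
        axes = self.fft_axes
        out = np.zeros(self.grid_shape, dtype=complex)
        for j in range(self.plan.n_bins):
            xb = self.motion.warp(rho, j)
            y = np.fft.ifftshift(self.coil_maps * xb[None], axes=axes)
            k = _fft.fftn(y, axes=axes, norm="ortho")
            k *= shifted[j][None, None]
            y = np.fft.fftshift(_fft.ifftn(k, axes=axes, norm="ortho"), axes=axes)
            s = np.sum(np.conj(self.coil_maps) * y, axis=0)
            out += self.motion.warp_adjoint(s, j)
        return out


def zero_filled_recon(b: BinnedKSpace, plan: SamplingPlan, coil_maps: np.ndarray,
                      fft_x: bool = True) -> np.ndarray:
    """Per-bin zero-filled images ``rho_ZF = C* F^-1 D^T W^T b``.

    Unacquired readouts — both those undersampled away and the entire
    region beyond the low-resolution shutter — contribute zeros, giving
    coil-combined bin images at the full high-resolution array size with
    no motion operator applied.
    """
    ident = MotionFieldSet.identity(plan.n_bins, coil_maps.shape[1:])
    op = EncodingOperator(plan, coil_maps, ident, fft_x=fft_x)
    return op.adjoint_bins(b)


def conjugate_gradient(apply_a, rhs: np.ndarray, x0: np.ndarray, n_iter: int):
    """Fixed-iteration CG for a Hermitian positive (semi)definite system.

    No early-exit tolerance: the iteration count is part of the unrolled
    architecture.  Returns ``(x, residual_norms)`` with the residual
    2-norm recorded before each iteration and after the last.
    """
    x = x0.astype(complex).copy()
    r = rhs - apply_a(x)
    p = r.copy()
    rs = float(np.real(np.vdot(r, r)))
    res = [np.sqrt(rs)]
    for _ in range(n_iter):
        ap = apply_a(p)
        denom = float(np.real(np.vdot(p, ap)))
        if denom <= 0 or rs == 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(np.real(np.vdot(r, r)))
        res.append(np.sqrt(rs_new))
        beta = rs_new / rs
        p = r + beta * p
        rs = rs_new
    return x, np.array(res)


def cg_solve_step1(E: EncodingOperator, b: BinnedKSpace, g: np.ndarray,
                   lam: float, n_iter: int = 5, return_residuals: bool = False,
                   atb: np.ndarray | None = None):
    """ADMM Step 1: argmin_rho 1/2||E rho - b||^2 + lam/2||rho - g||^2.

    Solves the normal equations ``(E*E + lam I) rho = E*b + lam g`` by
    conjugate gradient initialized at ``g`` with a fixed iteration count
    (default 5).  ``atb`` may carry a precomputed ``E*b``.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rhs = (E.adjoint(b) if atb is None else atb) + lam * g
    x, res = conjugate_gradient(lambda v: E.normal(v) + lam * v, rhs, g, n_iter)
    return (x, res) if return_residuals else x


def iterative_sense(zero_filled_bin: np.ndarray, bin_acq: BinAcquisition,
                    coil_maps: np.ndarray, n_iter: int = 10,
                    tikhonov: float = 1e-6, fft_x: bool = True,
                    return_residuals: bool = False):
    """Single-bin iterative SENSE from its zero-filled image.

    CG solution of ``(E_i* E_i + eps I) x = rho_ZF,i`` where ``E_i`` has
    no motion operator; the small Tikhonov term conditions the
    rank-deficient undersampled single-bin system.  Default 10
    iterations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    grid = coil_maps.shape[1:]
    axes = (1, 2, 3) if fft_x else (2, 3)

    def apply_a(x):
        k = fftc(coil_maps * x[None], axes=axes)
        s = _gather(k, bin_acq)
        kk = _scatter(s, bin_acq, grid[1:])
        img = ifftc(kk, axes=axes)
        return np.sum(np.conj(coil_maps) * img, axis=0) + tikhonov * x

    x, res = conjugate_gradient(apply_a, zero_filled_bin.astype(complex),
                                np.zeros(grid, dtype=complex), n_iter)
    return (x, res) if return_residuals else x
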