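"""Shared numerical conventions.

The whole package uses a centered, unitary discrete Fourier transform:
the DC sample sits at index ``N // 2`` on every axis and ``F* == F^-1``
exactly, so adjoint tests close to machine precision and zero-padding
k-space is amplitude-stable.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft

GOLDEN_ANGLE_DEG = 111.24611797498108  # 180 * (3 - sqrt(5))


def fftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centered unitary FFT over ``axes`` (default: all)."""
    if axes is None:
        axes = tuple(range(x.ndim))
    return np.fft.fftshift(
        _fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centered unitary inverse FFT over ``axes`` (default: all)."""
    if axes is None:
        axes = tuple(range(x.ndim))
    return np.fft.fftshift(
        _fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def centered_freqs(n: int) -> np.ndarray:
    """Integer frequency indices with DC at position ``n // 2``."""
    return np.arange(n) - n // 2


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def real_dot(a: np.ndarray, b: np.ndarray) -> float:
    """Real part of the complex inner product <a, b>."""
    return float(np.real(np.vdot(a, b)))


def next_multiple(n: int, base: int = 16) -> int:
    return int(-(-n // base) * base)
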