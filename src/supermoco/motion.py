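"""Non-rigid motion: diffeomorphic fields, warping and its exact adjoint.

Deformations are represented as dense voxel-unit displacement fields
``u`` with the warped image sampled at ``x + u(x)`` by trilinear
interpolation (clamped at the volume edges).  Diffeomorphic fields are
built from stationary velocity fields through scaling and squaring,
which guarantees invertibility of the continuous flow; the numerical
inverse is simply the exponential of the negated velocity.

The warp operator ``M`` is linear in the image, and its adjoint ``M*``
is implemented as the exact transpose of the trilinear interpolation
matrix (a scatter of the interpolation weights), so that
``<M x, y> == <x, M* y>`` holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionFieldSet",
    "warp_image",
    "warp_adjoint",
    "warp_with_grad",
    "warp_displacement",
    "scaling_and_squaring",
    "invert_displacement",
    "jacobian_determinant",
    "charbonnier_loss",
]


def _trilinear(disp: np.ndarray):
    """Flat corner indices and weights of trilinear sampling at x + u(x).

    Returns ``(idx, w)`` each of shape (8, nvox).  Sample positions are
    clamped to the valid index range (zero-flux boundary handling).
    """
    if disp.ndim != 4 or disp.shape[0] != 3:
        raise ValueError(f"displacement must have shape (3, X, Y, Z), got {disp.shape}")
    shape = disp.shape[1:]
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    pos = [np.clip(g + d, 0.0, n - 1.0) for g, d, n in zip(grids, disp, shape)]
    lo = [np.minimum(np.floor(p).astype(np.intp), n - 2) if n > 1 else np.zeros_like(p, dtype=np.intp)
          for p, n in zip(pos, shape)]
    frac = [p - l for p, l in zip(pos, lo)]

    idx = np.empty((8,) + shape, dtype=np.intp)
    w = np.empty((8,) + shape, dtype=np.float64)
    sy = shape[2]
    sx = shape[1] * shape[2]
    base = lo[0] * sx + lo[1] * sy + lo[2]
    for c in range(8):
        bx, by, bz = (c >> 2) & 1, (c >> 1) & 1, c & 1
        idx[c] = base + bx * sx + by * sy + bz
        w[c] = (
            (frac[0] if bx else 1.0 - frac[0])
            * (frac[1] if by else 1.0 - frac[1])
            * (frac[2] if bz else 1.0 - frac[2])
        )
    nv = int(np.prod(shape))
    return idx.reshape(8, nv), w.reshape(8, nv), frac, lo


def warp_image(image: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Resample ``image`` at ``x + disp(x)`` (trilinear, clamped edges).

    Linear in the image; works for real or complex volumes.
    """
    if image.shape != disp.shape[1:]:
        raise ValueError(f"image shape {image.shape} does not match field {disp.shape[1:]}")
    idx, w, _, _ = _trilinear(np.asarray(disp, dtype=np.float64))
    flat = image.reshape(-1)
    out = np.zeros(flat.shape[0], dtype=image.dtype if np.iscomplexobj(image) else np.result_type(image, np.float64))
    for c in range(8):
        out += w[c] * flat[idx[c]]
    return out.reshape(image.shape)


def warp_adjoint(image: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`warp_image` in its image argument."""
    if image.shape != disp.shape[1:]:
        raise ValueError(f"image shape {image.shape} does not match field {disp.shape[1:]}")
    idx, w, _, _ = _trilinear(np.asarray(disp, dtype=np.float64))
    flat = image.reshape(-1)
    out = np.zeros(flat.shape[0], dtype=np.result_type(image, np.float64))
    for c in range(8):
        np.add.at(out, idx[c], w[c] * flat)
    return out.reshape(image.shape)


def warp_with_grad(image: np.ndarray, disp: np.ndarray):
    """Warped image plus its pointwise derivative w.r.t. the displacement.

    Returns ``(out, dout)`` with ``dout`` of shape (3, X, Y, Z): the
    spatial gradient of the interpolant evaluated at the sample points.
    Real images only (used by the differentiable motion branch).
    """
    disp = np.asarray(disp, dtype=np.float64)
    idx, w, frac, _ = _trilinear(disp)
    flat = np.asarray(image, dtype=np.float64).reshape(-1)
    shape = image.shape
    out = np.zeros(flat.shape[0])
    dout = np.zeros((3, flat.shape[0]))
    f = [fr.reshape(-1) for fr in frac]
    for c in range(8):
        bx, by, bz = (c >> 2) & 1, (c >> 1) & 1, c & 1
        vals = flat[idx[c]]
        wx = f[0] if bx else 1.0 - f[0]
        wy = f[1] if by else 1.0 - f[1]
        wz = f[2] if bz else 1.0 - f[2]
        out += wx * wy * wz * vals
        dout[0] += (1.0 if bx else -1.0) * wy * wz * vals
        dout[1] += wx * (1.0 if by else -1.0) * wz * vals
        dout[2] += wx * wy * (1.0 if bz else -1.0) * vals
    return out.reshape(shape), dout.reshape((3,) + shape)


def warp_displacement(u: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Warp each component of a vector field ``u`` by ``disp``."""
    return np.stack([warp_image(u[d], disp) for d in range(3)])


def scaling_and_squaring(velocity: np.ndarray, n_steps: int = 6) -> np.ndarray:
    """Exponentiate a stationary velocity field: ``phi = exp(v)``.

    Scales ``v`` by ``2**-n_steps`` and self-composes the map
    ``n_steps`` times via trilinear resampling.  The continuous flow of
    any velocity field is a diffeomorphism, so the output displacement
    is invertible (``exp(-v)`` is its inverse) up to interpolation
    error.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    velocity = np.asarray(velocity, dtype=np.float64)
    if not np.all(np.isfinite(velocity)):
        raise ValueError("velocity field contains non-finite values")
    disp = velocity / (2.0 ** n_steps)
    for _ in range(n_steps):
        disp = disp + warp_displacement(disp, disp)
    return disp


def invert_displacement(disp: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Fixed-point numerical inverse: ``inv(x) = -disp(x + inv(x))``."""
    inv = -disp
    for _ in range(n_iter):
        inv = -warp_displacement(disp, inv)
    return inv


def jacobian_determinant(disp: np.ndarray) -> np.ndarray:
    """Finite-difference Jacobian determinant of ``phi(x) = x + u(x)``."""
    grads = np.empty((3, 3) + disp.shape[1:])
    for i in range(3):
        gj = np.gradient(disp[i], axis=(0, 1, 2))
        for j in range(3):
            grads[i, j] = gj[j] + (1.0 if i == j else 0.0)
    j = grads
    return (
        j[0, 0] * (j[1, 1] * j[2, 2] - j[1, 2] * j[2, 1])
        - j[0, 1] * (j[1, 0] * j[2, 2] - j[1, 2] * j[2, 0])
        + j[0, 2] * (j[1, 0] * j[2, 1] - j[1, 1] * j[2, 0])
    )


def charbonnier_loss(x: np.ndarray, y: np.ndarray, epsilon: float = 1e-3) -> float:
    """Mean of ``sqrt(|x - y|^2 + eps^2)`` — a smooth L1 surrogate."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    # hypot(|d|, eps) == sqrt(|d|^2 + eps^2) but returns eps exactly at d=0
    return float(np.mean(np.hypot(np.abs(x - y), epsilon)))


class CachedWarp:
    """Precomputed trilinear coefficients of one displacement field.

    Amortizes coefficient computation when the same field warps many
    volumes (every CG iteration of a reconstruction re-applies M)."""

    def __init__(self, disp: np.ndarray):
        self.shape = disp.shape[1:]
        self.idx, self.w, _, _ = _trilinear(np.asarray(disp, dtype=np.float64))

    def apply(self, image: np.ndarray) -> np.ndarray:
        flat = image.reshape(-1)
        out = self.w[0] * flat[self.idx[0]]
        for c in range(1, 8):
            out = out + self.w[c] * flat[self.idx[c]]
        return out.reshape(self.shape)

    def adjoint(self, image: np.ndarray) -> np.ndarray:
        flat = image.reshape(-1)
        out = np.zeros(flat.shape[0], dtype=np.result_type(image, np.float64))
        for c in range(8):
            np.add.at(out, self.idx[c], self.w[c] * flat)
        return out.reshape(self.shape)


@dataclass
class MotionFieldSet:
    """Dense reference-to-bin displacement fields for all respiratory bins.

    ``fields[i]`` maps reference-bin coordinates into bin ``i``, so that
    ``warp_image(ref, fields[i])`` produces the bin-``i`` image; the
    reference field is identically zero.
    """

    fields: np.ndarray  # (Nb, 3, X, Y, Z), voxel units
    reference: int = 0

    def __post_init__(self):
        self.fields = np.asarray(self.fields, dtype=np.float64)
        if self.fields.ndim != 5 or self.fields.shape[1] != 3:
            raise ValueError("fields must have shape (Nb, 3, X, Y, Z)")
        if not 0 <= self.reference < self.n_bins:
            raise ValueError("reference bin out of range")

    @property
    def n_bins(self) -> int:
        return self.fields.shape[0]

    @property
    def grid_shape(self):
        return self.fields.shape[2:]

    @classmethod
    def identity(cls, n_bins: int, grid_shape, reference: int = 0) -> "MotionFieldSet":
        return cls(np.zeros((n_bins, 3) + tuple(grid_shape)), reference)

    def _warper(self, bin_index: int) -> CachedWarp:
        cache = getattr(self, "_warpers", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_warpers", cache)
        if bin_index not in cache:
            cache[bin_index] = CachedWarp(self.fields[bin_index])
        return cache[bin_index]

    def warp(self, image: np.ndarray, bin_index: int) -> np.ndarray:
        return self._warper(bin_index).apply(image)

    def warp_adjoint(self, image: np.ndarray, bin_index: int) -> np.ndarray:
        return self._warper(bin_index).adjoint(image)
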