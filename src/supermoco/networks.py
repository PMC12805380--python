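"""The two learned components and their differentiable geometry ops.

* :class:`MotionNet` — diffeomorphic respiratory motion estimation: a
  3-D U-Net consumes a (reference, moving) pair of magnitude volumes
  (padded to a pooling-friendly shape and internally 2x-downsampled),
  predicts a bounded stationary velocity field, and a scaling-and-
  squaring layer exponentiates it, guaranteeing an invertible
  deformation for any network parameters.  The inverse deformation is
  the exponential of the negated velocity and is returned alongside.
* :class:`SRDenoiser` — the super-resolving denoiser S: a residual 3-D
  U-Net on the 2-channel (real, imag) representation of a complex
  volume.
* :class:`FeatureExtractorStub` — a frozen, seeded stack of 2-D
  convolutions exposing five feature maps for the perceptual loss, used
  where pretrained perceptual-feature weights are not available;
  deterministic and download-free.

Whether the motion network should see complex, magnitude or two-channel
input is an open choice; magnitude is used here since registration is
contrast-driven.
"""

from __future__ import annotations

import numpy as np

from .motion import MotionFieldSet, warp_adjoint, warp_image, warp_with_grad
from .nn import Tensor, UNet, avg_pool, concat, custom_op, upsample_nearest
from .nn.layers import ConvLayer, Module
from .utils import next_multiple

__all__ = [
    "warp_op",
    "warp_vec_op",
    "scaling_and_squaring_t",
    "MotionNet",
    "SRDenoiser",
    "FeatureExtractorStub",
    "estimate_motion_fields",
]


def warp_op(image: Tensor, disp: Tensor) -> Tensor:
    """Differentiable trilinear warp of a real 3-D image tensor."""
    out, dout = warp_with_grad(image.data, disp.data)

    def vjp(g):
        gi = warp_adjoint(g, disp.data) if image.requires_grad else None
        gd = g[None] * dout if disp.requires_grad else None
        return gi, gd

    return custom_op((image, disp), out, vjp)


def warp_vec_op(u: Tensor, phi: Tensor) -> Tensor:
    """Warp each component of field ``u`` by ``phi`` (both differentiable)."""
    outs, douts = zip(*(warp_with_grad(u.data[i], phi.data) for i in range(3)))
    out = np.stack(outs)

    def vjp(g):
        gu = np.stack([warp_adjoint(g[i], phi.data) for i in range(3)]) if u.requires_grad else None
        gphi = sum(g[i][None] * douts[i] for i in range(3)) if phi.requires_grad else None
        return gu, gphi

    return custom_op((u, phi), out, vjp)


def scaling_and_squaring_t(velocity: Tensor, n_steps: int = 6) -> Tensor:
    """Differentiable exponential of a stationary velocity field."""
    disp = velocity * (1.0 / 2.0**n_steps)
    for _ in range(n_steps):
        disp = disp + warp_vec_op(disp, disp)
    return disp


def _smoothing_kernel(channels: int, nd: int = 3) -> Tensor:
    """Fixed per-channel 3-point binomial smoothing kernel (non-trainable)."""
    k1 = np.array([0.25, 0.5, 0.25])
    k = k1
    for _ in range(nd - 1):
        k = np.multiply.outer(k, k1)
    w = np.zeros((channels, channels) + (3,) * nd)
    for c in range(channels):
        w[c, c] = k
    return Tensor(w, requires_grad=False)


class MotionNet(Module):
    """Velocity-predicting U-Net with a scaling-and-squaring layer.

    ``input_shape`` fixes the padded geometry fed to the network
    (default: each dim rounded up to a multiple of 16); inputs are
    average-pooled by 2 internally and the output displacement is
    upsampled by 2 (values doubled) and cropped back.
    ``v_max`` bounds the velocity magnitude (voxels) through a tanh so
    the discrete exponential stays well-resolved.
    """

    def __init__(self, base_ch: int = 16, levels: int = 3, n_steps: int = 6,
                 v_max: float = 4.0, input_shape=None, seed: int = 0):
        self.unet = UNet(nd=3, in_ch=2, out_ch=3, base_ch=base_ch, levels=levels,
                         seed=seed, final_gain=0.1)
        self.n_steps = n_steps
        self.v_max = float(v_max)
        self.input_shape = tuple(input_shape) if input_shape is not None else None
        self._smooth = _smoothing_kernel(3)

    def _padded_shape(self, shape):
        if self.input_shape is not None:
            return self.input_shape
        return tuple(next_multiple(n, 16) for n in shape)

    def velocity(self, ref_mag: np.ndarray, mov_mag: np.ndarray) -> Tensor:
        """Bounded, smoothed velocity field on the half-resolution grid."""
        if ref_mag.shape != mov_mag.shape:
            raise ValueError("volume pair shapes differ")
        scale = max(float(np.max(ref_mag)), float(np.max(mov_mag)), 1e-12)
        pair = np.stack([ref_mag / scale, mov_mag / scale])
        target = self._padded_shape(ref_mag.shape)
        if any(t < s for t, s in zip(target, ref_mag.shape)):
            raise ValueError(f"input geometry {ref_mag.shape} exceeds the network contract {target}")
        padw = [(0, 0)] + [((t - s) // 2, t - s - (t - s) // 2) for t, s in zip(target, ref_mag.shape)]
        x = Tensor(np.pad(pair, padw), requires_grad=False)
        x = avg_pool(x, 2)
        raw = self.unet(x)
        v = (raw * (1.0 / self.v_max)).tanh() * self.v_max
        from .nn.autodiff import conv

        return conv(v, self._smooth)

    def displacement(self, ref_mag: np.ndarray, mov_mag: np.ndarray,
                     inverse: bool = False):
        """Full-resolution displacement (and its inverse) as tensors.

        Returns ``(disp, disp_inv)`` mapping reference coordinates to the
        moving volume and back; ``disp_inv`` is None unless requested.
        """
        target = self._padded_shape(ref_mag.shape)
        v = self.velocity(ref_mag, mov_mag)
        crop_off = [(t - s) // 2 for t, s in zip(target, ref_mag.shape)]

        def _exp(vel):
            d = scaling_and_squaring_t(vel, self.n_steps)
            d = upsample_nearest(d, 2) * 2.0
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(crop_off, ref_mag.shape))
            return d.crop(sl)

        disp = _exp(v)
        disp_inv = _exp(v * (-1.0)) if inverse else None
        return disp, disp_inv


def estimate_motion_fields(aux_bins: np.ndarray, net: MotionNet,
                           reference: int) -> MotionFieldSet:
    """Pairwise motion estimation from de-noised auxiliary bin images.

    For each non-reference bin the network consumes the (reference, bin)
    magnitude pair and the exponential of the predicted velocity gives
    the reference-to-bin displacement; the reference field is zero.
    Works with untrained networks (the output is then merely a valid —
    diffeomorphic — deformation, not a useful one).
    """
    aux = np.abs(np.asarray(aux_bins))
    nb = aux.shape[0]
    if not 0 <= reference < nb:
        raise ValueError("reference bin out of range")
    fields = np.zeros((nb, 3) + aux.shape[1:])
    for j in range(nb):
        if j == reference:
            continue
        disp, _ = net.displacement(aux[reference], aux[j])
        fields[j] = disp.data
    return MotionFieldSet(fields, reference=reference)


class SRDenoiser(Module):
    """Residual super-resolving denoiser on 2-channel complex volumes."""

    def __init__(self, base_ch: int = 16, levels: int = 3, seed: int = 100):
        self.unet = UNet(nd=3, in_ch=2, out_ch=2, base_ch=base_ch, levels=levels,
                         seed=seed, final_gain=0.1)

    def apply_t(self, x: Tensor) -> Tensor:
        """Complex tensor in, complex tensor out (residual connection)."""
        ch = x.to_channels()
        return (ch + self.unet(ch)).to_complex()

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.apply_t(Tensor(np.asarray(x, dtype=complex))).data


class FeatureExtractorStub(Module):
    """Frozen seeded convolutional pyramid with five named feature maps.

    Maps are exposed under the keys (1,1), (2,2), (3,3), (4,3), (5,4) —
    block and convolution indices of the five perceptual-loss taps.
    Input is a single-channel 2-D slice; each block halves the spatial
    size.  All parameters are fixed at construction (never trained).

    ``feature_gain`` scales every exposed map so feature-space losses on
    unit-magnitude images land in the numeric regime the loss weights
    were balanced for (with unscaled maps the kernel-norm term would
    dwarf the perceptual term and training would only decay weights).
    """

    KEYS = ((1, 1), (2, 2), (3, 3), (4, 3), (5, 4))

    def __init__(self, seed: int = 7, widths=(4, 8, 8, 8, 8), feature_gain: float = 25.0):
        rng = np.random.default_rng(seed)
        self.feature_gain = float(feature_gain)
        self.blocks = []
        ch = 1
        for w in widths:
            layer = ConvLayer(ch, w, 3, nd=2, rng=rng)
            layer.weight.requires_grad = False
            layer.bias.requires_grad = False
            self.blocks.append(layer)
            ch = w

    def features(self, x: Tensor) -> dict:
        """x: (H, W) real tensor -> dict of five (C, h, w) feature maps."""
        out = {}
        h = x.unsqueeze(0)
        for key, block in zip(self.KEYS, self.blocks):
            h = block(h).leaky_relu()
            out[key] = h * self.feature_gain
            if min(h.shape[1:]) >= 4 and all(n % 2 == 0 for n in h.shape[1:]):
                h = avg_pool(h, 2)
        return out
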