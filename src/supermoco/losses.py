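"""Training losses: perceptual, pre-training and end-to-end objectives.

The perceptual loss compares two complex volumes through five named
feature maps of a 2-D feature extractor, with slices along the fully
sampled readout (x) direction forming the batch.  The printed feature
weights make each weighted feature-map loss contribute approximately
equally.  Regularization is the sum of squared convolution-kernel
entries (standard weight decay; read here as the squared l2 norm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, add_n
from .nn.layers import Module

__all__ = [
    "LossWeights",
    "perceptual_loss",
    "kernel_norm_t",
    "pretrain_loss",
    "end_to_end_loss",
    "charbonnier_loss_t",
]

#: feature-map weights psi_{c,d}: block/conv index -> weight
DEFAULT_PSI = {(1, 1): 3.0, (2, 2): 0.04, (3, 3): 0.016, (4, 3): 0.01, (5, 4): 14.0}


@dataclass
class LossWeights:
    """Perceptual feature weights and the loss-combination weights.

    ``gamma = (100, 1)`` weights (perceptual, SR-net kernel norm) in the
    pre-training objective; ``eta = (10, 1, 100)`` weights (perceptual,
    kernel norm of both networks, motion Charbonnier) in the end-to-end
    objective.
    """

    psi: dict = field(default_factory=lambda: dict(DEFAULT_PSI))
    gamma: tuple = (100.0, 1.0)
    eta: tuple = (10.0, 1.0, 100.0)

    def __post_init__(self):
        if len(self.psi) != 5:
            raise ValueError("exactly five perceptual feature maps are expected")
        if any(w <= 0 for w in self.psi.values()):
            raise ValueError("feature weights must be positive")
        if any(w <= 0 for w in self.gamma) or any(w <= 0 for w in self.eta):
            raise ValueError("loss weights must be positive")


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def perceptual_loss(rho_hr, rho_out, extractor, weights: LossWeights | None = None) -> Tensor:
    """Weighted five-feature-map loss between two (complex) volumes.

    Per feature map: the mean squared error over the map's spatial
    dimensions and channels, averaged over the x-slice batch; the total
    is the psi-weighted sum over the five maps.  Accepts numpy arrays or
    autodiff tensors; gradients flow through ``rho_out``.
    """
    weights = weights or LossWeights()
    hr = _as_tensor(rho_hr)
    out = _as_tensor(rho_out)
    if hr.shape != out.shape:
        raise ValueError("volume shapes differ")
    hr_m = hr.magnitude() if np.iscomplexobj(hr.data) else hr
    out_m = out.magnitude() if np.iscomplexobj(out.data) else out

    nx = hr.shape[0]
    per_map: dict = {k: [] for k in weights.psi}
    for x in range(nx):
        f_hr = extractor.features(hr_m.crop((x,)))
        f_out = extractor.features(out_m.crop((x,)))
        for key in weights.psi:
            if key not in f_hr:
                raise KeyError(f"extractor does not provide feature map {key}")
            per_map[key].append((f_hr[key] - f_out[key]).square().mean())
    terms = []
    for key, psi in weights.psi.items():
        terms.append(add_n(per_map[key]) * (psi / nx))
    return add_n(terms)


def kernel_norm_t(*modules: Module) -> Tensor:
    """Sum of squared convolution-kernel entries as a graph node."""
    terms = [p.square().sum() for m in modules for p in m.parameters()]
    return add_n(terms) if terms else Tensor(np.array(0.0))


def pretrain_loss(l_perc, kernel_norm, weights: LossWeights | None = None):
    """gamma1 * L_perc + gamma2 * ||kernels||^2 (defaults 100 and 1)."""
    weights = weights or LossWeights()
    g1, g2 = weights.gamma
    return l_perc * g1 + kernel_norm * g2


def end_to_end_loss(l_perc, kernel_norm_both, l_mot, weights: LossWeights | None = None):
    """eta1 * L_perc + eta2 * L_reg + eta3 * L_mot (defaults 10, 1, 100).

    ``l_mot`` is the self-supervised Charbonnier warp loss; no ground
    truth motion fields enter the objective.
    """
    weights = weights or LossWeights()
    e1, e2, e3 = weights.eta
    return l_perc * e1 + kernel_norm_both * e2 + l_mot * e3


def charbonnier_loss_t(x: Tensor, y: Tensor, epsilon: float = 1e-3) -> Tensor:
    """Differentiable Charbonnier loss between real tensors."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return ((x - y).square() + epsilon**2).sqrt().mean()
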