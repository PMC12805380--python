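"""Overlapping patches along the fully sampled readout (x) direction.

Undersampling and resolution-loss artifacts propagate in the y-z plane
only, so volumes are processed in x-slabs of fixed thickness (a multiple
of 16 so pooling layers never meet odd sizes).  On recombination a
five-voxel edge layer of each patch is discarded, leaving a four-voxel
overlap between adjacent retained intervals which is averaged; the first
and last patches keep their outer edge voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatchPlan", "patch_starts", "retained_interval", "split_into_patches", "recombine_patches"]


@dataclass
class PatchPlan:
    thickness: int = 32
    discard: int = 5
    overlap: int = 4

    def __post_init__(self):
        if self.thickness % 16:
            raise ValueError("patch thickness must be a multiple of 16")
        if self.retained <= 0 or self.stride <= 0:
            raise ValueError("discard/overlap leave no usable patch interior")

    @property
    def retained(self) -> int:
        """Interior width kept from each patch (thickness - 2*discard)."""
        return self.thickness - 2 * self.discard

    @property
    def stride(self) -> int:
        """Start-to-start distance between adjacent patches."""
        return self.retained - self.overlap


def patch_starts(x_dim: int, plan: PatchPlan):
    """Start offsets of all patches covering an x-axis of length x_dim."""
    if x_dim < plan.thickness:
        raise ValueError(f"x dimension {x_dim} smaller than patch thickness {plan.thickness}")
    starts = [0]
    while starts[-1] + plan.thickness < x_dim:
        nxt = min(starts[-1] + plan.stride, x_dim - plan.thickness)
        starts.append(nxt)
    # drop patches made redundant by the clamped last start, so no voxel
    # is covered by more than two retained intervals (pairwise averaging
    # of identical values is exact in floating point)
    pruned = [starts[0]]
    for i in range(1, len(starts) - 1):
        prev_end = pruned[-1] + plan.thickness - plan.discard
        next_start = starts[i + 1] + plan.discard
        if next_start > prev_end:  # removing starts[i] would break coverage
            pruned.append(starts[i])
    if len(starts) > 1:
        pruned.append(starts[-1])
    return pruned


def retained_interval(start: int, x_dim: int, plan: PatchPlan, index: int, n_patches: int):
    """Half-open retained x-interval of patch ``index``.

    Interior patches drop ``discard`` voxels from each edge; the first
    and last patches keep their outer edge.
    """
    lo = 0 if index == 0 else start + plan.discard
    hi = x_dim if index == n_patches - 1 else start + plan.thickness - plan.discard
    return lo, hi


def split_into_patches(volume: np.ndarray, plan: PatchPlan, axis: int = 0):
    """Cut ``volume`` into overlapping x-slabs of ``plan.thickness``."""
    x_dim = volume.shape[axis]
    starts = patch_starts(x_dim, plan)
    patches = []
    for s in starts:
        sl = [slice(None)] * volume.ndim
        sl[axis] = slice(s, s + plan.thickness)
        patches.append(volume[tuple(sl)].copy())
    return patches, starts


def recombine_patches(patches, starts, x_dim: int, plan: PatchPlan, axis: int = 0) -> np.ndarray:
    """Discard patch edges and average the retained-interval overlaps.

    Exact inverse of :func:`split_into_patches` when the per-patch
    processing is the identity.
    """
    if len(patches) != len(starts):
        raise ValueError("patch and start counts differ")
    shape = list(patches[0].shape)
    shape[axis] = x_dim
    acc = np.zeros(shape, dtype=patches[0].dtype)
    count = np.zeros(x_dim)
    n = len(patches)
    for i, (p, s) in enumerate(zip(patches, starts)):
        if p.shape[axis] != plan.thickness:
            raise ValueError("patch thickness inconsistent with plan")
        lo, hi = retained_interval(s, x_dim, plan, i, n)
        sl_out = [slice(None)] * acc.ndim
        sl_out[axis] = slice(lo, hi)
        sl_in = [slice(None)] * acc.ndim
        sl_in[axis] = slice(lo - s, hi - s)
        acc[tuple(sl_out)] += p[tuple(sl_in)]
        count[lo:hi] += 1
    if (count == 0).any():
        raise ValueError("retained intervals do not cover the x-axis")
    cshape = [1] * acc.ndim
    cshape[axis] = x_dim
    return acc / count.reshape(cshape)
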