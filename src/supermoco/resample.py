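"""Retrospective down-sampling and k-space padding.

Training pairs are built by degrading high-resolution acquisitions so
they match prospective low-resolution scans: the phase-encode plane is
segmented into 20 concentric elliptic annuli, everything outside the
outermost (SR-scaled) annulus is discarded, and within each annulus
acquired lines are randomly retained until the measured density profile
of a prospective-style mask is matched.  Retained lines keep their
measured values bit-exactly — no sample is ever synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import RawKSpace
from .trajectory import elliptical_shutter
from .utils import as_rng, next_multiple

__all__ = [
    "AnnulusDensityProfile",
    "measure_density_profile",
    "retrospective_downsample",
    "pad_kspace_to_multiple16",
    "pad_raw_to_multiple16",
]


@dataclass
class AnnulusDensityProfile:
    """Mean sampling density in each of ``n_annuli`` elliptic annuli."""

    densities: np.ndarray
    n_annuli: int = 20
    outer_boundary: float = 1.0

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=float)
        if len(self.densities) != self.n_annuli:
            raise ValueError("density count does not match n_annuli")
        if ((self.densities < 0) | (self.densities > 1)).any():
            raise ValueError("densities must lie in [0, 1]")


def _norm_radius(pts_y, pts_z, grid_yz):
    ny, nz = grid_yz
    return np.sqrt(((pts_y - ny // 2) / (ny / 2.0)) ** 2 + ((pts_z - nz // 2) / (nz / 2.0)) ** 2)


def _annulus_of(r, n_annuli, outer=1.0):
    idx = np.floor(r / outer * n_annuli).astype(int)
    idx[np.isclose(r, outer)] = n_annuli - 1
    return idx


def measure_density_profile(mask_yz: np.ndarray, n_annuli: int = 20) -> AnnulusDensityProfile:
    """Fraction of acquired points per equal-width elliptic annulus."""
    mask_yz = np.asarray(mask_yz, dtype=bool)
    grid = mask_yz.shape
    shutter = elliptical_shutter(grid)
    if not shutter.any():
        raise ValueError("empty elliptical shutter")
    yy, zz = np.nonzero(shutter)
    r = _norm_radius(yy, zz, grid)
    ann = _annulus_of(np.clip(r, 0, 1), n_annuli)
    densities = np.zeros(n_annuli)
    for j in range(n_annuli):
        sel = ann == j
        if sel.any():
            densities[j] = mask_yz[yy[sel], zz[sel]].mean()
    return AnnulusDensityProfile(densities, n_annuli)


@dataclass
class DownsampleReport:
    achieved: np.ndarray
    target: np.ndarray
    shortfall: np.ndarray  # lines missing per annulus where target > available


def retrospective_downsample(
    raw: RawKSpace,
    sr_factor,
    target_profile: AnnulusDensityProfile,
    seed: int = 0,
):
    """Degrade a high-resolution acquisition to a low-resolution one.

    ``sr_factor`` (scalar or per-axis (fy, fz)) scales the annuli: the
    outermost annulus boundary becomes the inscribed ellipse of the new
    low-resolution grid.  Within each annulus a random subset of the
    acquired lines is retained to match the target density; if the
    target exceeds availability all available lines are kept and the
    shortfall recorded.  Deterministic for a fixed seed.

    Returns ``(raw_lr, report)``.
    """
    fy, fz = (sr_factor, sr_factor) if np.isscalar(sr_factor) else sr_factor
    nx, ny, nz = raw.grid_shape
    src_grid = raw.lr_grid_yz
    lr_grid = (2 * int(round(src_grid[0] / fy / 2)), 2 * int(round(src_grid[1] / fz / 2)))
    if min(lr_grid) < 2:
        raise ValueError("SR factor leaves no low-resolution grid")

    pts = np.concatenate([t for t in raw.traj_lines if t.size], axis=0)
    uniq = np.unique(pts, axis=0)
    # normalized radius on the scaled (low-res) shutter
    sy = (uniq[:, 0] - src_grid[0] // 2) / (lr_grid[0] / 2.0)
    sz = (uniq[:, 1] - src_grid[1] // 2) / (lr_grid[1] / 2.0)
    r = np.sqrt(sy**2 + sz**2)

    n_ann = target_profile.n_annuli
    inside = r <= 1.0
    ann = _annulus_of(np.clip(r, 0, 1), n_ann)

    lr_shutter = elliptical_shutter(lr_grid)
    yy, zz = np.nonzero(lr_shutter)
    r_grid = _norm_radius(yy, zz, lr_grid)
    ann_grid = _annulus_of(np.clip(r_grid, 0, 1), n_ann)

    rng = as_rng(seed)
    keep_mask = np.zeros(len(uniq), dtype=bool)
    achieved = np.zeros(n_ann)
    shortfall = np.zeros(n_ann, dtype=int)
    for j in range(n_ann):
        total_j = int((ann_grid == j).sum())
        avail = np.where(inside & (ann == j))[0]
        want = int(round(target_profile.densities[j] * total_j))
        if want >= len(avail):
            chosen = avail
            shortfall[j] = want - len(avail)
        else:
            chosen = rng.choice(avail, size=want, replace=False)
        keep_mask[chosen] = True
        achieved[j] = len(chosen) / total_j if total_j else 0.0

    kept = {tuple(p) for p in uniq[keep_mask]}
    off_y = src_grid[0] // 2 - lr_grid[0] // 2
    off_z = src_grid[1] // 2 - lr_grid[1] // 2
    new_k, new_t = [], []
    for h in range(raw.n_heartbeats):
        t = raw.traj_lines[h]
        sel = np.array([tuple(p) in kept for p in t], dtype=bool) if t.size else np.zeros(0, bool)
        tt = t[sel] - np.array([off_y, off_z])
        ok = (tt[:, 0] >= 0) & (tt[:, 0] < lr_grid[0]) & (tt[:, 1] >= 0) & (tt[:, 1] < lr_grid[1])
        new_t.append(tt[ok])
        new_k.append(raw.kspace[h][sel][ok])

    raw_lr = RawKSpace(
        kspace=new_k,
        traj_lines=new_t,
        inav=raw.inav,
        grid_shape=raw.grid_shape,
        voxel_size_mm=raw.voxel_size_mm,
        lr_grid_yz=lr_grid,
    )
    report = DownsampleReport(achieved=achieved, target=target_profile.densities.copy(), shortfall=shortfall)
    return raw_lr, report


def pad_kspace_to_multiple16(b, plan):
    """Zero-pad the ky/kz grid to the next multiple of 16.

    Readout indices are re-centered on the padded grid and sample values
    are rescaled so voxel amplitudes of the unitary-DFT reconstruction
    are preserved.  Returns ``(b_padded, plan_padded)``.
    """
    from .trajectory import BinAcquisition, SamplingPlan

    ny, nz = plan.grid_yz
    ny2, nz2 = next_multiple(ny), next_multiple(nz)
    if (ny2, nz2) == (ny, nz):
        return b.copy(), plan
    off = np.array([ny2 // 2 - ny // 2, nz2 // 2 - nz // 2])
    scale = np.sqrt((ny2 * nz2) / (ny * nz))
    bins = [
        BinAcquisition(readouts=acq.readouts + off, weights=acq.weights.copy(),
                       sources=acq.sources)
        for acq in plan.bins
    ]
    plan2 = SamplingPlan(
        n_bins=plan.n_bins, bins=bins, grid_yz=(ny2, nz2), lr_grid_yz=plan.lr_grid_yz,
        hard_assignment=plan.hard_assignment, reference_bin=plan.reference_bin,
    )
    b2 = type(b)([d * scale for d in b.data], b.hybrid)
    return b2, plan2


def pad_raw_to_multiple16(raw: RawKSpace) -> RawKSpace:
    """Pad the target high-resolution grid of a raw container to x16."""
    nx, ny, nz = raw.grid_shape
    ny2, nz2 = next_multiple(ny), next_multiple(nz)
    if (ny2, nz2) == (ny, nz):
        return raw
    scale = np.sqrt((ny2 * nz2) / (ny * nz))
    return RawKSpace(
        kspace=[k * scale for k in raw.kspace],
        traj_lines=[t.copy() for t in raw.traj_lines],
        inav=raw.inav,
        grid_shape=(nx, ny2, nz2),
        voxel_size_mm=raw.voxel_size_mm,
        lr_grid_yz=raw.lr_grid_yz,
    )
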