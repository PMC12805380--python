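"""VD-CASPR sampling, navigator translation estimation, k-space phase
correction, and soft-gated respiratory binning.

The trajectory is Cartesian: every sampled (ky, kz) phase-encode point
carries a fully sampled kx readout line.  Sampling is restricted to the
elliptical shutter inscribed in the rectangular phase-encode grid, with
spiral-like interleaves rotated by the golden angle from heartbeat to
heartbeat and a sampling density that decreases with elliptical radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utils import GOLDEN_ANGLE_DEG, as_rng, centered_freqs

__all__ = [
    "VDCASPRTrajectory",
    "RespiratorySignal",
    "SamplingPlan",
    "BinAcquisition",
    "elliptical_shutter",
    "elliptical_radius",
    "generate_vdcaspr",
    "estimate_inav_translations",
    "apply_translational_correction",
    "phase_shift_kline",
    "soft_gated_binning",
    "compute_acceleration_factors",
]


def elliptical_radius(grid_yz) -> np.ndarray:
    """Normalized elliptical radius of every (ky, kz) point.

    The shutter ellipse is inscribed in the rectangular grid with the
    center at (ny//2, nz//2); radius 1 is the shutter boundary.
    """
    ny, nz = grid_yz
    y = (np.arange(ny) - ny // 2) / (ny / 2.0)
    z = (np.arange(nz) - nz // 2) / (nz / 2.0)
    return np.sqrt(y[:, None] ** 2 + z[None, :] ** 2)


def elliptical_shutter(grid_yz) -> np.ndarray:
    """Boolean mask of the inscribed elliptical shutter."""
    return elliptical_radius(grid_yz) <= 1.0


@dataclass
class VDCASPRTrajectory:
    """Per-heartbeat ordered (ky, kz) readout indices on a Cartesian grid."""

    grid_yz: tuple
    readouts: list  # list of (R_h, 2) int arrays, one per heartbeat
    nominal_undersampling: float = 1.0

    def __post_init__(self):
        self.grid_yz = tuple(int(n) for n in self.grid_yz)
        shutter = elliptical_shutter(self.grid_yz)
        for r in self.readouts:
            if r.size and not shutter[r[:, 0], r[:, 1]].all():
                raise ValueError("trajectory contains points outside the elliptical shutter")

    @property
    def n_heartbeats(self) -> int:
        return len(self.readouts)

    @property
    def shutter(self) -> np.ndarray:
        return elliptical_shutter(self.grid_yz)

    def unique_points(self) -> np.ndarray:
        pts = np.concatenate([r for r in self.readouts if r.size], axis=0)
        return np.unique(pts, axis=0)

    def achieved_undersampling(self) -> float:
        return float(self.shutter.sum()) / len(self.unique_points())


def generate_vdcaspr(
    grid_yz,
    undersampling: float,
    n_heartbeats: int,
    readouts_per_heartbeat: int,
    seed=0,
    density_exponent: float = 2.0,
) -> VDCASPRTrajectory:
    """Variable-density Cartesian sampling with spiral profile order.

    The sampled set is drawn without replacement with probability
    ``(1 - r)^p`` in elliptical radius ``r`` (the innermost points are
    always kept), then ordered into spiral arms; successive heartbeats
    acquire successive arms, rotated by the golden angle (~111.25 deg).
    With enough heartbeats every selected point is acquired, so the
    achieved undersampling (shutter points / unique sampled points)
    equals the request up to rounding.
    """
    if undersampling < 1:
        raise ValueError("undersampling must be >= 1")
    if min(grid_yz) < 4:
        raise ValueError("phase-encode grid too small for a VD-CASPR interleave")
    rng = as_rng(seed)
    shutter = elliptical_shutter(grid_yz)
    pts = np.argwhere(shutter)
    n_pts = len(pts)
    if n_pts < 8:
        raise ValueError("elliptical shutter too small to host one interleave")
    readouts_per_heartbeat = min(readouts_per_heartbeat, n_pts)

    ny, nz = grid_yz
    ry = (pts[:, 0] - ny // 2) / (ny / 2.0)
    rz = (pts[:, 1] - nz // 2) / (nz / 2.0)
    r = np.sqrt(ry**2 + rz**2)
    theta = np.arctan2(rz, ry)

    n_keep = int(round(n_pts / undersampling))
    n_keep = max(n_keep, min(n_pts, readouts_per_heartbeat))
    if n_keep >= n_pts:
        keep = np.arange(n_pts)
    else:
        # fully retain the innermost points, variable density outside
        order_r = np.argsort(r, kind="stable")
        n_center = min(n_keep, max(1, int(0.02 * n_pts)))
        center = order_r[:n_center]
        rest = order_r[n_center:]
        w = (1.0 - r[rest] + 1e-3) ** density_exponent
        chosen = rng.choice(rest, size=n_keep - n_center, replace=False, p=w / w.sum())
        keep = np.concatenate([center, chosen])

    kr, ktheta = r[keep], theta[keep]
    n_arms = max(1, -(-len(keep) // readouts_per_heartbeat))  # ceil
    golden = np.deg2rad(GOLDEN_ANGLE_DEG)
    arm_angles = (np.arange(n_arms) * golden) % (2 * np.pi)
    # spiral key: azimuth unwound by one turn center-to-edge
    kappa = (ktheta - 2 * np.pi * kr) % (2 * np.pi)
    dist = np.abs(kappa[:, None] - arm_angles[None, :])
    dist = np.minimum(dist, 2 * np.pi - dist)
    arm_of = np.argmin(dist, axis=1)

    arms = []
    for a in range(n_arms):
        members = np.where(arm_of == a)[0]
        members = members[np.argsort(kr[members], kind="stable")]  # center-out
        arms.append(pts[keep[members]])

    readouts = [arms[h % n_arms].copy() for h in range(n_heartbeats)]
    return VDCASPRTrajectory(tuple(grid_yz), readouts, float(undersampling))


@dataclass
class RespiratorySignal:
    """Per-heartbeat foot-head (x) and left-right (y) displacement, voxels."""

    fh: np.ndarray
    lr: np.ndarray

    def __post_init__(self):
        self.fh = np.asarray(self.fh, dtype=np.float64)
        self.lr = np.asarray(self.lr, dtype=np.float64)
        if self.fh.shape != self.lr.shape or self.fh.ndim != 1:
            raise ValueError("fh and lr must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return len(self.fh)


def estimate_inav_translations(
    inavs: np.ndarray,
    template_box=None,
    reference: int = 0,
    max_shift: int = 8,
    scale: float = 1.0,
) -> RespiratorySignal:
    """Estimate per-heartbeat in-plane translations from 2-D navigators.

    Normalized cross-correlation of a template (a box in the reference
    frame) against every frame over integer shifts, refined to subpixel
    precision with a parabolic fit of the correlation peak.

    Parameters
    ----------
    inavs : (n_heartbeats, ny, nx) array
        Navigator frames; axis 2 is foot-head (x), axis 1 left-right (y).
    template_box : ((y0, y1), (x0, x1)) or None
        Template region in the reference frame; default central half.
    scale : float
        Voxels per navigator pixel (navigators are often coarser than
        the imaging grid); estimated shifts are multiplied by it.
    """
    inavs = np.asarray(inavs, dtype=np.float64)
    if inavs.ndim != 3 or inavs.shape[0] < 1:
        raise ValueError("need a (n_heartbeats, ny, nx) navigator stack")
    nh, ny, nx = inavs.shape
    if template_box is None:
        template_box = ((ny // 4, ny - ny // 4), (nx // 4, nx - nx // 4))
    (y0, y1), (x0, x1) = template_box
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError("template box outside navigator frame")
    template = inavs[reference, y0:y1, x0:x1]
    tc = template - template.mean()
    tnorm = np.linalg.norm(tc)
    if tnorm == 0:
        raise ValueError("flat (zero-variance) template")

    # limit shifts so the shifted box stays inside the frame
    smax_y = min(max_shift, y0, ny - y1)
    smax_x = min(max_shift, x0, nx - x1)
    sy = np.arange(-smax_y, smax_y + 1)
    sx = np.arange(-smax_x, smax_x + 1)

    fh = np.zeros(nh)
    lr = np.zeros(nh)
    for h in range(nh):
        scores = np.full((len(sy), len(sx)), -np.inf)
        for i, dy in enumerate(sy):
            for j, dx in enumerate(sx):
                patch = inavs[h, y0 + dy : y1 + dy, x0 + dx : x1 + dx]
                pc = patch - patch.mean()
                denom = np.linalg.norm(pc) * tnorm
                scores[i, j] = (pc * tc).sum() / denom if denom > 0 else -np.inf
        iy, ix = np.unravel_index(np.argmax(scores), scores.shape)
        dy = float(sy[iy]) + _parabolic_offset(scores[:, ix], iy)
        dx = float(sx[ix]) + _parabolic_offset(scores[iy, :], ix)
        lr[h] = dy * scale
        fh[h] = dx * scale
    # report relative to the reference heartbeat so that any systematic
    # bias of the parabolic refinement cancels (identical frames -> 0)
    fh -= fh[reference]
    lr -= lr[reference]
    return RespiratorySignal(fh=fh, lr=lr)


def _parabolic_offset(line: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(line) - 1:
        return 0.0
    c0, c1, c2 = line[i - 1], line[i], line[i + 1]
    denom = c0 - 2 * c1 + c2
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    return float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))


def phase_shift_kline(
    kline: np.ndarray, ky: int, kz: int, shift_xy, grid_shape
) -> np.ndarray:
    """Apply the k-space linear phase shifting the image by ``shift_xy``.

    ``kline`` is the complex kx readout (possibly with leading axes) at
    phase-encode point (ky, kz); a shift (sx, sy) in image space equals
    multiplication by ``exp(-2*pi*i*(kx*sx/Nx + ky*sy/Ny))`` with
    centered frequency indices.
    """
    nx, ny, _ = grid_shape
    sx, sy = shift_xy
    kx = centered_freqs(nx)
    kyc = ky - ny // 2
    phase = np.exp(-2j * np.pi * (kx * sx / nx + kyc * sy / ny))
    return kline * phase


def apply_translational_correction(raw, signal: RespiratorySignal):
    """Phase-shift each heartbeat's readouts to align the heart in-plane.

    Each heartbeat's samples are multiplied by the linear k-space phase
    that shifts its image content by minus the estimated (foot-head,
    left-right) displacement.  Unitary on every sample (magnitudes are
    unchanged) and exactly inverted by correcting with the negated
    signal.
    """
    from .phantom import RawKSpace  # local import to avoid a cycle

    if len(signal) != raw.n_heartbeats:
        raise ValueError("signal length does not match heartbeat count")
    nx, ny, nz = raw.grid_shape
    kx = centered_freqs(nx)
    corrected = []
    for h in range(raw.n_heartbeats):
        sx, sy = -signal.fh[h], -signal.lr[h]
        # centered ky index is grid-independent: lr and hr grids share DC
        ky = raw.traj_lines[h][:, 0] - raw.lr_grid_yz[0] // 2
        # phase over (readout_in_hb, kx); broadcast across coils
        phase = np.exp(-2j * np.pi * (kx[None, :] * sx / nx + ky[:, None] * sy / ny))
        corrected.append(raw.kspace[h] * phase[:, None, :])
    return RawKSpace(
        kspace=corrected,
        traj_lines=[t.copy() for t in raw.traj_lines],
        inav=raw.inav,
        grid_shape=raw.grid_shape,
        voxel_size_mm=raw.voxel_size_mm,
        lr_grid_yz=raw.lr_grid_yz,
    )


@dataclass
class BinAcquisition:
    """Readouts contributing to one respiratory bin with soft weights.

    Each (ky, kz) point appears at most once per bin; repeated
    acquisitions of the same line within the bin are consolidated into a
    weighted average on assembly (``sources`` records the contributing
    (heartbeat, row, weight) triples of every readout).
    """

    readouts: np.ndarray  # (K_i, 2) int, (ky, kz) on the high-res grid
    weights: np.ndarray  # (K_i,) in [0, 1]
    sources: list = None  # per readout: list of (heartbeat, row, weight)

    @property
    def n_samples(self) -> int:
        return len(self.readouts)


@dataclass
class SamplingPlan:
    """Per-bin acquired readouts, soft-gating weights and SR geometry.

    ``grid_yz`` is the high-resolution phase-encode grid on which
    readout indices live; ``lr_grid_yz`` is the acquired low-resolution
    grid, whose inscribed ellipse is the low-res shutter (everything
    outside it was never acquired).
    """

    n_bins: int
    bins: list  # list of BinAcquisition
    grid_yz: tuple
    lr_grid_yz: tuple
    hard_assignment: np.ndarray = field(default=None)  # (n_heartbeats,) bin ids
    reference_bin: int = 0

    @property
    def k_per_bin(self):
        return [b.n_samples for b in self.bins]

    @property
    def total_samples(self) -> int:
        return int(sum(self.k_per_bin))

    def unique_points(self) -> np.ndarray:
        pts = np.concatenate([b.readouts for b in self.bins], axis=0)
        return np.unique(pts, axis=0)


def soft_gated_binning(
    traj: VDCASPRTrajectory,
    signal: RespiratorySignal,
    n_bins: int,
    hr_grid_yz=None,
    weight_floor: float = 0.05,
) -> SamplingPlan:
    """Sort heartbeats into equally populated bins with soft weights.

    Hard assignment splits heartbeats into ``n_bins`` quantile groups of
    the foot-head signal (populations differ by at most one; ties broken
    by heartbeat order).  Each heartbeat additionally receives Gaussian
    weights ``exp(-d^2 / (2 sigma^2))`` in every bin, where ``d`` is its
    distance from the bin center and ``sigma`` half the bin's quantile
    width; weights below ``weight_floor`` are truncated to zero.  The
    reference bin is end-expiration: the bin with the smallest mean
    foot-head displacement.
    """
    nh = traj.n_heartbeats
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > nh:
        raise ValueError("more bins than heartbeats")
    if len(signal) != nh:
        raise ValueError("signal length does not match heartbeat count")

    order = np.argsort(signal.fh, kind="stable")
    groups = np.array_split(order, n_bins)
    hard = np.empty(nh, dtype=int)
    for j, g in enumerate(groups):
        hard[g] = j

    centers = np.array([signal.fh[g].mean() for g in groups])
    sigmas = np.array([(signal.fh[g].max() - signal.fh[g].min()) / 2.0 for g in groups])

    if hr_grid_yz is None:
        hr_grid_yz = traj.grid_yz
    off_y = hr_grid_yz[0] // 2 - traj.grid_yz[0] // 2
    off_z = hr_grid_yz[1] // 2 - traj.grid_yz[1] // 2

    bins = []
    for j in range(n_bins):
        contrib: dict = {}

        def _add(h, w):
            pts = traj.readouts[h]
            for row in range(len(pts)):
                key = (int(pts[row, 0]) + off_y, int(pts[row, 1]) + off_z)
                contrib.setdefault(key, []).append((h, row, w))

        for h in range(nh):
            if sigmas[j] > 0:
                w = float(np.exp(-((signal.fh[h] - centers[j]) ** 2) / (2 * sigmas[j] ** 2)))
            else:
                w = 1.0 if hard[h] == j else 0.0
            if w >= weight_floor:
                _add(h, w)
        if not contrib:
            # degenerate: keep the hard members regardless of the floor
            for h in np.where(hard == j)[0]:
                _add(h, 1.0)
        keys = sorted(contrib)
        readouts = np.array(keys, dtype=int).reshape(len(keys), 2)
        weights = np.array([np.mean([w for _, _, w in contrib[k]]) for k in keys])
        bins.append(
            BinAcquisition(
                readouts=readouts,
                weights=weights,
                sources=[contrib[k] for k in keys],
            )
        )

    reference = int(np.argmin(centers))
    return SamplingPlan(
        n_bins=n_bins,
        bins=bins,
        grid_yz=tuple(hr_grid_yz),
        lr_grid_yz=traj.grid_yz,
        hard_assignment=hard,
        reference_bin=reference,
    )


def compute_acceleration_factors(plan: SamplingPlan, hr_grid_yz=None, lr_grid_yz=None):
    """Acceleration accounting by exact point counting.

    Returns ``(vdcaspr_factor, sr_factor, overall)`` where the VD-CASPR
    factor is low-res shutter points over unique acquired points, the SR
    factor is high-res over low-res shutter points, and the overall
    acceleration is their product.
    """
    if hr_grid_yz is None:
        hr_grid_yz = plan.grid_yz
    if lr_grid_yz is None:
        lr_grid_yz = plan.lr_grid_yz
    if plan.total_samples == 0:
        raise ValueError("empty acquisition")
    hr_pts = int(elliptical_shutter(hr_grid_yz).sum())
    lr_pts = int(elliptical_shutter(lr_grid_yz).sum())
    if lr_pts == 0:
        raise ValueError("empty low-resolution shutter")
    n_unique = len(plan.unique_points())
    vdcaspr = lr_pts / n_unique
    sr = hr_pts / lr_pts
    return vdcaspr, sr, vdcaspr * sr
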