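"""Synthetic moving-heart phantom, coil maps, navigators and acquisition.

Generates everything a desk-scale end-to-end run needs without any
download: a complex 3-D anatomy with ellipsoidal chambers and one thin
bright vessel, a pseudo-periodic breathing signal, per-bin diffeomorphic
deformations (bulk foot-head/left-right translation plus a smooth
non-rigid component built by scaling-and-squaring, so ground-truth
invertibility holds by construction), smooth normalized coil maps, and a
simulated multi-coil Cartesian acquisition with 2-D coronal navigator
projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .motion import MotionFieldSet, scaling_and_squaring, warp_image
from .trajectory import RespiratorySignal, VDCASPRTrajectory
from .utils import as_rng, fftc

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RawKSpace",
    "generate_phantom",
    "simulate_coil_maps",
    "simulate_acquisition",
    "make_inav",
]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic moving phantom.

    ``motion_amplitude_vox`` is the peak foot-head breathing excursion in
    voxels; the left-right excursion is 0.4x that and the non-rigid
    component 0.3x.  ``noise_snr`` is mean |signal| over complex noise
    standard deviation (None for noiseless).
    """

    grid_shape: tuple = (16, 48, 32)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    n_bins: int = 4
    n_coils: int = 4
    n_heartbeats: int = 48
    motion_amplitude_vox: float = 2.0
    noise_snr: float | None = None
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be 3 dims, each >= 8")
        if self.n_bins < 1 or self.n_coils < 1:
            raise ValueError("n_bins and n_coils must be >= 1")
        if self.n_heartbeats < self.n_bins:
            raise ValueError("need at least as many heartbeats as bins")
        if self.motion_amplitude_vox < 0:
            raise ValueError("motion amplitude must be non-negative")
        if self.noise_snr is not None and self.noise_snr <= 0:
            raise ValueError("noise_snr must be positive")


@dataclass
class PhantomTruth:
    """Ground truth of one synthetic subject."""

    bin_images: np.ndarray  # (Nb, X, Y, Z) complex
    reference_bin: int
    true_fields: MotionFieldSet
    coil_maps: np.ndarray  # (Nc, X, Y, Z) complex, SOS-normalized
    breathing_signal: RespiratorySignal
    heartbeat_bins: np.ndarray  # (n_heartbeats,) bin state of each heartbeat
    spec: PhantomSpec = field(default=None, repr=False)

    @property
    def reference_image(self) -> np.ndarray:
        return self.bin_images[self.reference_bin]


@dataclass
class RawKSpace:
    """Raw multi-coil Cartesian acquisition with trajectory and navigators.

    ``kspace[h]`` is the (R_h, Nc, Nx) complex block of heartbeat ``h``;
    each row is a fully sampled kx line at the (ky, kz) point stored in
    ``traj_lines[h]`` (0-based indices on the acquired low-resolution
    phase-encode grid ``lr_grid_yz``).  ``grid_shape`` is the target
    high-resolution image grid.
    """

    kspace: list
    traj_lines: list
    inav: np.ndarray
    grid_shape: tuple
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    lr_grid_yz: tuple = None

    def __post_init__(self):
        if self.lr_grid_yz is None:
            self.lr_grid_yz = (self.grid_shape[1], self.grid_shape[2])
        self.grid_shape = tuple(self.grid_shape)
        self.lr_grid_yz = tuple(self.lr_grid_yz)
        if len(self.kspace) != len(self.traj_lines):
            raise ValueError("kspace and trajectory heartbeat counts differ")

    @property
    def n_heartbeats(self) -> int:
        return len(self.kspace)

    @property
    def n_coils(self) -> int:
        return self.kspace[0].shape[1]

    def trajectory(self) -> VDCASPRTrajectory:
        return VDCASPRTrajectory(self.lr_grid_yz, [t.copy() for t in self.traj_lines])


def _ellipsoid(grid_shape, center, radii) -> np.ndarray:
    x, y, z = np.meshgrid(*[np.arange(n, dtype=float) for n in grid_shape], indexing="ij")
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _vessel_tube(grid_shape, rng) -> np.ndarray:
    """A curved bright tube of 2-voxel diameter for sharpness tests."""
    nx, ny, nz = grid_shape
    t = np.linspace(0.0, 1.0, 4 * max(grid_shape))
    cx = 0.2 * nx + 0.6 * nx * t
    cy = 0.5 * ny + 0.18 * ny * np.sin(2 * np.pi * 0.4 * t + 0.5)
    cz = 0.55 * nz + 0.12 * nz * np.cos(2 * np.pi * 0.3 * t)
    mark = np.zeros(grid_shape, dtype=bool)
    ix = np.clip(np.round(cx).astype(int), 0, nx - 1)
    iy = np.clip(np.round(cy).astype(int), 0, ny - 1)
    iz = np.clip(np.round(cz).astype(int), 0, nz - 1)
    mark[ix, iy, iz] = True
    dist = ndimage.distance_transform_edt(~mark)
    return dist <= 1.0


def _reference_anatomy(spec: PhantomSpec, rng) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    img = np.zeros(spec.grid_shape)
    img += 0.25 * _ellipsoid(spec.grid_shape, (nx / 2, ny / 2, nz / 2), (nx / 2.2, ny / 2.3, nz / 2.3))
    img += 0.45 * _ellipsoid(spec.grid_shape, (nx / 2, 0.42 * ny, 0.45 * nz), (nx / 4.5, ny / 5, nz / 4.5))
    img += 0.35 * _ellipsoid(spec.grid_shape, (0.45 * nx, 0.62 * ny, 0.5 * nz), (nx / 6, ny / 7, nz / 6))
    img[_vessel_tube(spec.grid_shape, rng)] = 1.2
    img = ndimage.gaussian_filter(img, sigma=0.6)
    # smooth low-order phase so the object is genuinely complex
    phase = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=max(spec.grid_shape) / 4)
    phase = 0.5 * phase / (np.abs(phase).max() + 1e-12)
    return img * np.exp(1j * phase)


def _breathing_signal(spec: PhantomSpec, rng) -> RespiratorySignal:
    """Pseudo-periodic breathing: two sinusoids with seeded phase jitter."""
    t = np.arange(spec.n_heartbeats, dtype=float)
    a = spec.motion_amplitude_vox
    jit1 = 0.3 * rng.standard_normal()
    jit2 = 0.3 * rng.standard_normal()
    wave = 0.7 * np.sin(2 * np.pi * 0.11 * t + jit1) + 0.3 * np.sin(2 * np.pi * 0.043 * t + jit2)
    wave = wave + 0.05 * rng.standard_normal(spec.n_heartbeats)
    fh = a * (wave - wave.min()) / max(np.ptp(wave), 1e-12) if a > 0 else np.zeros_like(wave)
    lr = 0.4 * fh
    return RespiratorySignal(fh=fh, lr=lr)


def _quantile_groups(values: np.ndarray, n_bins: int):
    order = np.argsort(values, kind="stable")
    return np.array_split(order, n_bins)


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Deterministically build a multi-bin moving phantom from its spec.

    The reference (end-expiration) volume is deformed into each bin by a
    bulk in-plane translation from the breathing signal plus a smooth
    non-rigid component obtained by exponentiating a low-spatial-
    frequency random velocity field scaled with respiratory depth, so
    every true field is invertible by construction.
    """
    rng = as_rng(spec.seed)
    ref = _reference_anatomy(spec, rng)
    signal = _breathing_signal(spec, rng)
    groups = _quantile_groups(signal.fh, spec.n_bins)
    hb_bins = np.empty(spec.n_heartbeats, dtype=int)
    for j, g in enumerate(groups):
        hb_bins[g] = j
    centers_fh = np.array([signal.fh[g].mean() for g in groups])
    centers_lr = np.array([signal.lr[g].mean() for g in groups])
    reference = int(np.argmin(centers_fh))

    # unit-amplitude smooth random velocity for the non-rigid component
    vel = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=min(spec.grid_shape) / 3)
         for _ in range(3)]
    )
    vel /= np.abs(vel).max() + 1e-12

    span = max(np.abs(centers_fh - centers_fh[reference]).max(), 1e-12)
    fields = np.zeros((spec.n_bins, 3) + spec.grid_shape)
    for j in range(spec.n_bins):
        if j == reference or spec.motion_amplitude_vox == 0:
            continue
        depth = (centers_fh[j] - centers_fh[reference]) / span
        nonrigid = scaling_and_squaring(depth * 0.3 * spec.motion_amplitude_vox * vel)
        fields[j] = nonrigid
        # warp(ref, d) samples ref(x + d): an object displaced by +t in
        # bin j needs d = -t, so navigator estimates carry the sign of t
        fields[j, 0] -= centers_fh[j] - centers_fh[reference]
        fields[j, 1] -= centers_lr[j] - centers_lr[reference]
    true_fields = MotionFieldSet(fields, reference=reference)

    bin_images = np.empty((spec.n_bins,) + spec.grid_shape, dtype=complex)
    for j in range(spec.n_bins):
        if j == reference or spec.motion_amplitude_vox == 0:
            bin_images[j] = ref
        else:
            bin_images[j] = warp_image(ref, fields[j])

    coil_maps = simulate_coil_maps(spec.grid_shape, spec.n_coils, seed=rng)
    return PhantomTruth(
        bin_images=bin_images,
        reference_bin=reference,
        true_fields=true_fields,
        coil_maps=coil_maps,
        breathing_signal=signal,
        heartbeat_bins=hb_bins,
        spec=spec,
    )


def simulate_coil_maps(grid_shape, n_coils: int, seed=0) -> np.ndarray:
    """Smooth complex coil maps with per-voxel sum-of-squares exactly 1."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    grid_shape = tuple(grid_shape)
    if n_coils == 1:
        return np.ones((1,) + grid_shape, dtype=complex)
    rng = as_rng(seed)
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(*[np.linspace(-1, 1, n) for n in grid_shape], indexing="ij")
    maps = np.empty((n_coils,) + grid_shape, dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + 0.3 * rng.standard_normal()
        py, pz = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        px = 0.4 * rng.standard_normal()
        mag = np.exp(-(((x - px) ** 2) + (y - py) ** 2 + (z - pz) ** 2) / 1.8)
        phs = 0.6 * (x * np.cos(ang) + y * np.sin(ang)) + 0.2 * rng.standard_normal()
        maps[c] = (0.2 + mag) * np.exp(1j * phs)
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / sos


def make_inav(volume: np.ndarray, downsample: int = 2) -> np.ndarray:
    """Simulated 2-D coronal navigator: central-slab mean projection.

    Magnitude of the mean over z of the volume, block-averaged to a
    ``downsample``-times coarser (y, x) frame.
    """
    proj = np.abs(volume).mean(axis=2).T  # (y, x)
    ny, nx = proj.shape
    d = downsample
    proj = proj[: ny - ny % d, : nx - nx % d]
    return proj.reshape(ny // d, d, nx // d, d).mean(axis=(1, 3))


def simulate_acquisition(
    truth: PhantomTruth,
    trajectory: VDCASPRTrajectory,
    noise_snr: float | None = None,
    seed: int = 0,
    inav_downsample: int = 2,
):
    """Sample multi-coil k-space of the moving phantom along a trajectory.

    Each heartbeat's readouts are drawn from the 3-D DFT of the bin
    image matching that heartbeat's respiratory state (translations
    included, so the downstream correction step has work to do), and a
    coronal navigator of the same state is recorded.  Optional i.i.d.
    complex Gaussian noise is added at the requested SNR
    (mean |signal| / noise std).

    Returns ``(raw, inavs)``; the navigator stack is also embedded in
    the returned :class:`RawKSpace`.
    """
    spec = truth.spec
    nx, ny, nz = truth.bin_images.shape[1:]
    if trajectory.n_heartbeats != len(truth.breathing_signal):
        raise ValueError("trajectory heartbeats do not match breathing signal length")
    off_y = ny // 2 - trajectory.grid_yz[0] // 2
    off_z = nz // 2 - trajectory.grid_yz[1] // 2

    nc = truth.coil_maps.shape[0]
    kvols = np.empty((truth.bin_images.shape[0], nc, nx, ny, nz), dtype=complex)
    for b in range(truth.bin_images.shape[0]):
        for c in range(nc):
            kvols[b, c] = fftc(truth.coil_maps[c] * truth.bin_images[b])

    rng = as_rng(seed)
    kspace, inavs = [], []
    for h in range(trajectory.n_heartbeats):
        state = truth.heartbeat_bins[h]
        pts = trajectory.readouts[h]
        ky = pts[:, 0] + off_y
        kz = pts[:, 1] + off_z
        if (ky < 0).any() or (ky >= ny).any() or (kz < 0).any() or (kz >= nz).any():
            raise ValueError("trajectory indices fall outside the image grid")
        lines = kvols[state][:, :, ky, kz]  # (nc, nx, R)
        kspace.append(np.ascontiguousarray(np.moveaxis(lines, 2, 0)))  # (R, nc, nx)
        inavs.append(make_inav(truth.bin_images[state], inav_downsample))

    if noise_snr is not None:
        if noise_snr <= 0:
            raise ValueError("noise_snr must be positive")
        all_mag = np.concatenate([np.abs(k).ravel() for k in kspace])
        sigma = all_mag.mean() / noise_snr
        for h in range(len(kspace)):
            n = rng.standard_normal(kspace[h].shape) + 1j * rng.standard_normal(kspace[h].shape)
            kspace[h] = kspace[h] + sigma / np.sqrt(2.0) * n

    inav = np.stack(inavs)
    raw = RawKSpace(
        kspace=kspace,
        traj_lines=[p.copy() for p in trajectory.readouts],
        inav=inav,
        grid_shape=(nx, ny, nz),
        voxel_size_mm=spec.voxel_size_mm if spec is not None else (1.0, 1.0, 1.0),
        lr_grid_yz=trajectory.grid_yz,
    )
    return raw, inav
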