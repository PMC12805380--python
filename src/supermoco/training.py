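"""Toy-scale training loops and synthetic dataset builders.

The loops implement the two-stage scheme: (1) pre-training of the
super-resolving denoiser on paired low/high-resolution volumes with the
perceptual + kernel-norm objective (Adam, default learning rate 1e-5),
and (2) end-to-end fine-tuning of the full unrolled framework (Adam,
default initial learning rate 1e-4 halved after a configurable epoch,
default 500) with the perceptual + regularization + self-supervised
motion objective.  Gradients flow through the conjugate-gradient data
consistency, the denoiser step and the warping layers.

Dataset builders emulate the study conditions on synthetic subjects:
either scheme "4x4" (approximately fully sampled low-resolution
acquisition, 4x super-resolution per phase-encode axis) or "2x2"
(4.5-fold undersampled, 2x super-resolution per axis); both target an
overall acceleration near 18.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .admm import Networks, ReconConfig, admm_reconstruct
from .losses import (
    LossWeights,
    charbonnier_loss_t,
    end_to_end_loss,
    kernel_norm_t,
    perceptual_loss,
    pretrain_loss,
)
from .motion import MotionFieldSet
from .networks import FeatureExtractorStub, MotionNet, SRDenoiser, warp_op
from .nn import Adam, Tensor, avg_pool
from .operators import BinnedKSpace, bin_kspace, iterative_sense, zero_filled_recon
from .patching import PatchPlan
from .phantom import PhantomSpec, generate_phantom, simulate_acquisition
from .trajectory import (
    apply_translational_correction,
    estimate_inav_translations,
    generate_vdcaspr,
    soft_gated_binning,
)
from .utils import as_rng

__all__ = [
    "TrainConfig",
    "TrainingSubject",
    "train_pretrain",
    "train_end_to_end",
    "train_motion_only",
    "make_sr_pairs",
    "make_training_subject",
    "SCHEMES",
]

#: prospective acquisition schemes: (sr factor per axis, VD-CASPR undersampling)
SCHEMES = {"4x4": (4, 1.15), "2x2": (2, 4.5)}


@dataclass
class TrainConfig:
    lr: float = 1e-5
    epochs: int = 50
    seed: int = 0
    schedule_epoch: int | None = None
    schedule_factor: float = 0.5
    weights: LossWeights = field(default_factory=LossWeights)


def train_pretrain(sr_net: SRDenoiser, pairs, config: TrainConfig,
                   extractor=None):
    """Pre-train the super-resolving denoiser on (low, high) pairs.

    Minimizes ``gamma1 L_perc + gamma2 ||kernels||^2`` per pair with
    Adam; returns the per-epoch mean loss history.  Deterministic for a
    fixed config seed (the only randomness is the parameter init, which
    belongs to the network).
    """
    if not pairs:
        raise ValueError("empty dataset")
    extractor = extractor or FeatureExtractorStub()
    opt = Adam(sr_net.parameters(), lr=config.lr)
    history = []
    for _ in range(config.epochs):
        losses = []
        for lo, hi in pairs:
            out = sr_net.apply_t(Tensor(np.asarray(lo, dtype=complex)))
            l_perc = perceptual_loss(hi, out, extractor, config.weights)
            loss = pretrain_loss(l_perc, kernel_norm_t(sr_net), config.weights)
            sr_net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history


def _multiscale_charbonnier(fixed_t: Tensor, aligned: Tensor, scales=(1, 2, 4)) -> Tensor:
    """Charbonnier alignment loss summed over coarsened copies.

    Coarse levels widen the capture range for displacements of several
    voxels (the standard multi-resolution registration device); the
    finest level keeps subvoxel accuracy.
    """
    f = fixed_t.unsqueeze(0)
    a = aligned.unsqueeze(0)
    terms = []
    for s in scales:
        if s > 1:
            if any(n % s for n in f.shape[1:]):
                continue
            terms.append(charbonnier_loss_t(avg_pool(f, s), avg_pool(a, s)))
        else:
            terms.append(charbonnier_loss_t(f, a))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


def train_motion_only(motion_net: MotionNet, pairs, config: TrainConfig,
                      scales=(1, 2, 4)):
    """Self-supervised registration training on (fixed, moving) pairs.

    Loss is the multi-scale Charbonnier distance between the fixed
    volume and the moving volume warped back by the inverse of the
    predicted deformation — no ground-truth fields enter.
    """
    if not pairs:
        raise ValueError("empty dataset")
    opt = Adam(motion_net.parameters(), lr=config.lr)
    history = []
    for _ in range(config.epochs):
        losses = []
        for fixed, moving in pairs:
            disp, disp_inv = motion_net.displacement(fixed, moving, inverse=True)
            aligned = warp_op(Tensor(np.asarray(moving, dtype=float)), disp_inv)
            loss = _multiscale_charbonnier(Tensor(np.asarray(fixed, dtype=float)), aligned, scales)
            motion_net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history


# ---------------------------------------------------------------------------
# synthetic dataset builders


def _lr_trajectory(grid_yz, scheme: str, n_heartbeats: int, seed):
    sr, under = SCHEMES[scheme]
    lr_grid = (grid_yz[0] // sr, grid_yz[1] // sr)
    n_pts = max(8, int(np.pi / 4 * lr_grid[0] * lr_grid[1]))
    per_hb = max(4, int(round(n_pts / under / max(n_heartbeats // 2, 1))))
    return generate_vdcaspr(lr_grid, under, n_heartbeats, per_hb, seed=seed)


def make_sr_pairs(n_pairs: int, grid_shape=(16, 32, 32), scheme: str = "2x2",
                  seed: int = 0, noise_snr: float | None = None):
    """Paired (low-res zero-filled, high-res) volumes from static phantoms."""
    rng = as_rng(seed)
    pairs = []
    for i in range(n_pairs):
        sub_seed = int(rng.integers(2**31 - 1))
        spec = PhantomSpec(grid_shape=grid_shape, n_bins=1, n_coils=1, n_heartbeats=4,
                           motion_amplitude_vox=0.0, noise_snr=noise_snr, seed=sub_seed)
        truth = generate_phantom(spec)
        traj = _lr_trajectory(grid_shape[1:], scheme, spec.n_heartbeats, sub_seed)
        raw, _ = simulate_acquisition(truth, traj, noise_snr=noise_snr, seed=sub_seed)
        plan = soft_gated_binning(raw.trajectory(), truth.breathing_signal, 1,
                                  hr_grid_yz=grid_shape[1:])
        zf = zero_filled_recon(bin_kspace(raw, plan), plan, truth.coil_maps)[0]
        pairs.append((zf, truth.reference_image))
    return pairs


@dataclass
class TrainingSubject:
    """Precomputed per-subject quantities for end-to-end training."""

    plan: object
    b_hybrid: BinnedKSpace
    zf_bins: np.ndarray
    coil_maps: np.ndarray
    hr_bins: np.ndarray  # ground-truth bin images on the high-res grid
    truth: object
    raw: object


def make_training_subject(seed: int, grid_shape=(16, 64, 32), scheme: str = "2x2",
                          n_bins: int = 4, n_coils: int = 4, n_heartbeats: int = 48,
                          motion_amplitude_vox: float = 2.0,
                          noise_snr: float | None = 30.0) -> TrainingSubject:
    """Simulate one subject and run the data path up to zero-filled bins."""
    spec = PhantomSpec(grid_shape=grid_shape, n_bins=n_bins, n_coils=n_coils,
                       n_heartbeats=n_heartbeats,
                       motion_amplitude_vox=motion_amplitude_vox,
                       noise_snr=noise_snr, seed=seed)
    truth = generate_phantom(spec)
    traj = _lr_trajectory(grid_shape[1:], scheme, n_heartbeats, seed)
    raw, _ = simulate_acquisition(truth, traj, noise_snr=noise_snr, seed=seed)
    nav_scale = grid_shape[0] / raw.inav.shape[2]
    signal = estimate_inav_translations(raw.inav, scale=nav_scale)
    raw_c = apply_translational_correction(raw, signal)
    plan = soft_gated_binning(raw_c.trajectory(), signal, n_bins, hr_grid_yz=grid_shape[1:])
    b = bin_kspace(raw_c, plan).to_hybrid()
    zf = zero_filled_recon(b, plan, truth.coil_maps, fft_x=False)
    return TrainingSubject(plan=plan, b_hybrid=b, zf_bins=zf, coil_maps=truth.coil_maps,
                           hr_bins=truth.bin_images, truth=truth, raw=raw)


def _random_patch_start(nx: int, thickness: int, rng) -> int:
    """A patch start inside the central 50% of the x-axis."""
    lo = nx // 4
    hi = 3 * nx // 4 - thickness
    if hi <= lo:
        return max(0, (nx - thickness) // 2)
    return int(rng.integers(lo, hi + 1))


def train_end_to_end(nets: Networks, subjects, config: TrainConfig,
                     recon_config: ReconConfig | None = None, extractor=None):
    """Fine-tune both networks through the full unrolled reconstruction.

    Each epoch draws, for every subject, a fresh patch of the configured
    thickness from the central 50% of the x-axis, reconstructs it with
    the current networks, and minimizes
    ``eta1 L_perc + eta2 L_reg + eta3 L_mot``.  The learning rate is
    multiplied by ``schedule_factor`` at ``schedule_epoch``.
    Returns a history of (total, perceptual, motion, lr) per epoch.
    """
    if not subjects:
        raise ValueError("empty dataset")
    recon_config = recon_config or ReconConfig()
    extractor = extractor or FeatureExtractorStub()
    params = []
    if nets.sr is not None:
        params += nets.sr.parameters()
    if nets.motion is not None:
        params += nets.motion.parameters()
    opt = Adam(params, lr=config.lr)
    rng = as_rng(config.seed)
    thickness = recon_config.patch.thickness
    history = []
    for epoch in range(config.epochs):
        if config.schedule_epoch is not None and epoch == config.schedule_epoch:
            opt.lr *= config.schedule_factor
        ep = []
        for sub in subjects:
            nx = sub.zf_bins.shape[1]
            s = _random_patch_start(nx, thickness, rng)
            sl = slice(s, s + thickness)
            coil_p = sub.coil_maps[:, sl]
            b_p = BinnedKSpace([d[:, :, sl] for d in sub.b_hybrid.data], hybrid=True)
            zf_p = sub.zf_bins[:, sl]
            ref = sub.plan.reference_bin
            hr_ref = np.abs(sub.hr_bins[ref, sl])

            if nets.motion is not None:
                aux = np.stack([
                    iterative_sense(zf_p[j], sub.plan.bins[j], coil_p,
                                    n_iter=recon_config.n_sense, fft_x=False)
                    for j in range(sub.plan.n_bins)
                ])
                aux = np.abs(aux)
                fields = np.zeros((sub.plan.n_bins, 3) + coil_p.shape[1:])
                mot_terms = []
                for j in range(sub.plan.n_bins):
                    if j == ref:
                        continue
                    disp, disp_inv = nets.motion.displacement(aux[ref], aux[j], inverse=True)
                    fields[j] = disp.data  # frozen inside E during backprop
                    aligned = warp_op(Tensor(np.abs(sub.hr_bins[j, sl])), disp_inv)
                    mot_terms.append(charbonnier_loss_t(Tensor(hr_ref), aligned))
                motion = MotionFieldSet(fields, reference=ref)
                l_mot = mot_terms[0] * (1.0 / len(mot_terms))
                for t in mot_terms[1:]:
                    l_mot = l_mot + t * (1.0 / len(mot_terms))
            else:
                motion = MotionFieldSet.identity(sub.plan.n_bins, coil_p.shape[1:], ref)
                l_mot = Tensor(np.array(0.0))

            rho = admm_reconstruct(b_p, sub.plan, coil_p, motion, nets.sr, recon_config)
            l_perc = perceptual_loss(sub.hr_bins[ref, sl], rho, extractor, config.weights)
            mods = [m for m in (nets.sr, nets.motion) if m is not None]
            loss = end_to_end_loss(l_perc, kernel_norm_t(*mods), l_mot, config.weights)
            for m in mods:
                m.zero_grad()
            loss.backward()
            opt.step()
            ep.append((loss.item(), l_perc.item(), l_mot.item()))
        history.append(tuple(np.mean(ep, axis=0)) + (opt.lr,))
    return history
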