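"""Reproducible desk-scale experiments exercising the full framework.

These are the study designs the package's own validation runs: a
known-motion recovery experiment for the motion branch and a toy
end-to-end training/benchmark for the complete reconstruction.  Problem
sizes are chosen so each experiment runs in minutes on one CPU while
still exercising every stage at full fidelity; the methods note
describes what these scales do and do not demonstrate.
"""

from __future__ import annotations

import numpy as np

from .admm import Networks, ReconConfig, super_moco_modl_reconstruct
from .evaluation import ROIMask, scaled_roi_mse, scaled_roi_ssim
from .motion import warp_image
from .networks import MotionNet, SRDenoiser
from .operators import iterative_sense
from .patching import PatchPlan
from .phantom import PhantomSpec, generate_phantom
from .training import (TrainConfig, make_training_subject, train_end_to_end,
                       train_motion_only)
from .utils import as_rng

__all__ = ["motion_recovery_experiment", "end_to_end_experiment"]


def _anatomy(seed, grid):
    spec = PhantomSpec(grid_shape=grid, n_bins=1, n_coils=1, n_heartbeats=4,
                       motion_amplitude_vox=0.0, seed=seed)
    return np.abs(generate_phantom(spec).reference_image)


def _translated(base, shift):
    grid = base.shape
    disp = np.stack([np.full(grid, s, dtype=float) for s in shift])
    return warp_image(base, disp)


def motion_recovery_experiment(seed: int = 0, grid=(16, 32, 16), n_anatomies: int = 3,
                               epochs: int = 1500, max_shift: float = 3.0):
    """Train the motion branch on synthetic in-plane translations and
    measure recovery on held-out shifts.

    Each epoch draws a fresh random (foot-head, left-right) translation
    up to ``max_shift`` voxels for every anatomy, so the network learns
    the registration map rather than memorizing pairs.  Held-out
    evaluation uses fixed shifts never seen in training; the recovered
    displacement is the mean of the predicted field over the anatomy
    (where image contrast constrains it).

    Returns a dict with per-pair errors and their mean/worst, plus the
    training-loss history endpoints.
    """
    rng = as_rng(seed)
    bases = [_anatomy(int(rng.integers(2**31 - 1)), grid) for _ in range(n_anatomies)]
    net = MotionNet(base_ch=8, levels=2, n_steps=4, seed=int(rng.integers(2**31 - 1)))

    first_loss = last_loss = None
    for ep in range(epochs):
        lr = 3e-3 if ep < epochs * 7 // 15 else (1e-3 if ep < epochs * 4 // 5 else 3e-4)
        pairs = []
        for b in bases:
            s = (rng.uniform(-max_shift, max_shift), rng.uniform(-max_shift, max_shift), 0.0)
            pairs.append((b, _translated(b, s)))
        h = train_motion_only(net, pairs, TrainConfig(lr=lr, epochs=1))
        if first_loss is None:
            first_loss = h[0]
        last_loss = h[0]

    held_out = [(3.0, 0.0, 0.0), (0.0, -3.0, 0.0), (-2.0, 1.0, 0.0), (0.0, 2.5, 0.0),
                (1.0, -2.0, 0.0), (-3.0, 0.0, 0.0), (2.0, 2.0, 0.0), (-1.5, -2.5, 0.0)]
    errors = []
    for i, s in enumerate(held_out):
        base = bases[i % n_anatomies]
        disp, _ = net.displacement(base, _translated(base, s))
        mask = base > 0.35
        est = np.array([disp.data[d][mask].mean() for d in range(3)])
        errors.append(float(np.abs(est - np.array(s)).max()))
    return {
        "per_pair_error_vox": errors,
        "mean_error_vox": float(np.mean(errors)),
        "worst_error_vox": float(np.max(errors)),
        "loss_first": first_loss,
        "loss_last": last_loss,
        "net": net,
    }


def _baselines(sub, recon_config):
    """Zero-filled and padded iterative-SENSE reference-bin images."""
    ref_bin = sub.plan.reference_bin
    zf = sub.zf_bins[ref_bin]
    sense = iterative_sense(zf, sub.plan.bins[ref_bin], sub.coil_maps,
                            n_iter=recon_config.n_sense, fft_x=False)
    return zf, sense


def end_to_end_experiment(seed: int = 0, n_subjects: int = 8, grid=(16, 64, 32),
                          epochs: int = 8, scheme: str = "2x2"):
    """Toy end-to-end training and held-out benchmark of the framework.

    Trains both networks through the unrolled reconstruction on
    ``n_subjects`` synthetic subjects, then reconstructs a held-out
    subject and compares ROI MSE against the zero-filled and padded
    iterative-SENSE baselines.  The held-out subject is additionally
    acquired with the alternative sampling scheme (approximately fully
    sampled with 4x4 super-resolution vs 4.5-fold undersampled with 2x2)
    at matched overall acceleration, reconstructed with the same trained
    framework.

    Returns a dict of ROI MSE values, SSIM, and acceleration factors.
    """
    rng = as_rng(seed)
    recon_config = ReconConfig(patch=PatchPlan(thickness=16, discard=2, overlap=2))
    sub_seeds = [int(rng.integers(2**31 - 1)) for _ in range(n_subjects + 1)]
    subjects = [make_training_subject(s, grid_shape=grid, scheme=scheme)
                for s in sub_seeds[:-1]]

    nets = Networks(motion=MotionNet(base_ch=4, levels=2, n_steps=4,
                                     seed=int(rng.integers(2**31 - 1))),
                    sr=SRDenoiser(base_ch=4, levels=2, seed=int(rng.integers(2**31 - 1))))
    history = train_end_to_end(nets, subjects,
                               TrainConfig(lr=1e-3, epochs=epochs,
                                           seed=int(rng.integers(2**31 - 1))),
                               recon_config=recon_config)

    held_seed = sub_seeds[-1]
    out = {"loss_history": [h[0] for h in history]}
    other = "4x4" if scheme == "2x2" else "2x2"
    for sch in (scheme, other):
        sub = make_training_subject(held_seed, grid_shape=grid, scheme=sch)
        truth = sub.truth
        roi = ROIMask(np.abs(truth.reference_image) > 0.15)
        diag: dict = {}
        rec = super_moco_modl_reconstruct(sub.raw, sub.coil_maps, nets,
                                          recon_config, diag)
        mse, _ = scaled_roi_mse(rec, truth.reference_image, roi)
        ssim, _ = scaled_roi_ssim(rec, truth.reference_image, roi)
        zf, sense = _baselines(sub, recon_config)
        mse_zf, _ = scaled_roi_mse(zf, truth.reference_image, roi)
        mse_sense, _ = scaled_roi_mse(sense, truth.reference_image, roi)
        out[sch] = {
            "mse_super_moco": mse,
            "ssim_super_moco": ssim,
            "mse_zero_filled": mse_zf,
            "mse_iterative_sense": mse_sense,
            "acceleration": diag["acceleration"],
        }
    out["scheme"] = scheme
    out["other_scheme"] = other
    out["nets"] = nets
    return out
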