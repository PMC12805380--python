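# Methods

## Problem and model

Free-breathing 3-D whole-heart cardiac MRI acquires multi-coil k-space
over many heartbeats while the heart moves with respiration. `supermoco`
reconstructs a high-resolution image of the end-expiration reference
state from a *low-resolution, undersampled* acquisition by solving

    argmin_{rho, omega}  1/2 ||E rho - b||^2 + mu/2 ||omega - S(omega)||^2
                         subject to  rho = omega,

where `rho` is the image, `b` the soft-gated, translational-corrected
k-space of all respiratory bins, `S` a learned super-resolving denoiser,
and the encoding operator factors as

    E = W D F C M

- `M`  — non-rigid warps from the reference bin into each respiratory bin
  (dense voxel-displacement fields; adjoint is the exact transpose of the
  trilinear interpolation matrix),
- `C`  — multiplication by coil sensitivity maps (sum-of-squares
  normalized to 1 per voxel),
- `F`  — centered, *unitary* 3-D DFT (DC at index `N//2`), so `F* = F^-1`
  exactly,
- `D`  — selection of acquired readouts, removing both undersampled-away
  center readouts and everything beyond the low-resolution elliptical
  shutter,
- `W`  — diagonal soft-gating weights in [0, 1], applied once in the
  forward model (the normal equations therefore see squared weights).

The split objective is minimized by scaled ADMM:

1. `rho <- argmin 1/2||E rho - b||^2 + lam/2||rho - (omega - a)||^2`,
   solved by conjugate gradient on `(E*E + lam I) rho = E*b + lam(omega - a)`
   with a **fixed** iteration count (no early exit — the loop is an
   unrolled, differentiable architecture);
2. `omega <- mu/(mu+lam) S(omega~) + lam/(mu+lam) omega~` with
   `omega~ = rho + a` — the closed-form solution of the Step-2
   subproblem under the assumption that `S` projects onto its output
   set; a convex combination for all positive `mu, lam`;
3. `a <- a + rho - omega`.

The loop stops after Step 1 of the final iteration, returning the
data-consistent iterate. Defaults follow the tuned values: `lam = 1.5`,
`mu = 10`, 4 ADMM iterations, 5 CG iterations in Step 1, 10 iterative-
SENSE iterations for the auxiliary de-noising, 4 respiratory bins.

**Dual-update sign.** The Step-3 update is implemented with the standard
scaled-ADMM sign `a + rho - omega`. The alternative printed form with a
plus sign in front of `omega` does not drive `rho` toward `omega` (the
constraint would never bind) and is treated as a typographical slip;
this is the single place where the implementation deviates from a
printed formula, and it is deliberate.

## Data path

1. **Navigator translation estimation.** A template box in the reference
   2-D coronal navigator is matched to every heartbeat's navigator by
   normalized cross-correlation over integer shifts with parabolic
   sub-pixel refinement; estimates are reported relative to the
   reference heartbeat so any refinement bias cancels. The method is a
   free design choice (the navigator registration algorithm is not
   pinned down by the reconstruction model).
2. **Translational correction.** Each heartbeat's samples are multiplied
   by the linear k-space phase that shifts its image by minus the
   estimated in-plane displacement; unitary on every sample.
3. **Soft-gated binning.** Heartbeats are hard-assigned to equally
   populated quantile bins of the foot-head signal (populations differ
   by at most one; ties broken by heartbeat order). Each heartbeat also
   receives Gaussian weights `exp(-d^2/(2 sigma^2))` in every bin, with
   `d` its distance from the bin center and `sigma` half the bin's
   quantile width, truncated to zero below 0.05. The exact soft-gating
   kernel in the literature varies; the Gaussian is the common
   convention. The reference bin is end-expiration (smallest mean
   foot-head displacement).
   Repeated acquisitions of the same (ky, kz) line within one bin are
   consolidated into a weight-weighted average before `W` applies — the
   standard multiple-averages treatment, which also keeps the
   zero-filled path exact under full sampling.
4. **Zero-filled bins** `rho_ZF = C* F^-1 D^T W^T b` at the full
   high-resolution array size. The identity `E*b = sum_i M_i* rho_ZF,i`
   is what allows zero-filled images, rather than raw k-space, to be
   the framework input; it is verified by test.
5. **Patching.** Because the readout (x) direction is fully sampled,
   samples are inverse-transformed along kx once (hybrid space) and the
   volume is processed in x-slabs of thickness 32 (a multiple of 16, so
   pooling layers never meet odd sizes). On recombination a five-voxel
   edge layer of each patch is discarded, leaving four-voxel overlaps
   that are averaged; near the volume end, patch starts are pruned so
   that no voxel is covered by more than two retained intervals, which
   makes the identity round trip exact in floating point (pairwise
   averages of equal values are exact; triple averages are not).
6. **Auxiliary images and motion estimation.** Each bin patch passes
   through iterative SENSE (CG on the single-bin normal equations with
   Tikhonov `1e-6` — undersampled single-bin systems are rank
   deficient), and pairs (reference, bin) of auxiliary magnitudes feed
   the motion network. Registration is contrast-driven, so magnitude
   input is used; complex phase is discarded for motion only.
7. **ADMM reconstruction** per patch, initialized at the
   motion-corrected adjoint `sum_i M_i* rho_ZF,i` (the initialization is
   an open choice; the adjoint is the best data-driven start and is
   consistent with the `E*b` identity). Data are normalized so the
   initial magnitude peak is 1; the scale is restored on output. Motion
   fields are estimated once and frozen through the loop.

## Learned components

**Motion network.** A 3-D U-Net (configurable width/depth; 16-channel,
3-level by default, desk-scale tests use 4–8 channels and 2 levels)
consumes the padded, 2x-downsampled (reference, moving) magnitude pair
and predicts a stationary velocity field, bounded through
`v_max * tanh(v / v_max)` (default `v_max = 4` voxels, the scale of
respiratory displacement at the resolutions used here) and smoothed by a
fixed binomial kernel. A scaling-and-squaring layer exponentiates the
velocity (default 6 steps; tests at toy scale use 4), which guarantees
an invertible deformation *for any network parameters*; the inverse
deformation is the exponential of the negated velocity and comes for
free. The displacement is upsampled by 2 (values doubled) and cropped to
the patch geometry.

**Super-resolving denoiser.** A residual 3-D U-Net on the 2-channel
(real, imaginary) representation: `S(x) = x + UNet(x)`, with a
small-gain final layer so the untrained network starts near the
identity — consistent with the role Step 2 assumes for `S`.

**Feature extractor.** The perceptual loss taps five feature maps named
(1,1), (2,2), (3,3), (4,3), (5,4) with weights 3.0, 0.04, 0.016, 0.01,
14.0 (weights chosen so each weighted term contributes comparably). The
extractor is pluggable; the packaged default is a frozen, seeded stack
of 2-D convolutions with pooling, which makes every run deterministic
and download-free. It is *not* a pretrained perceptual network and is
labelled accordingly; any 2-D extractor exposing the five maps can be
substituted. The feature-map MSE is normalized by `1/(Nx W H)` with
x-slices as the batch; the channel dimension (absent from the printed
normalization) is averaged.

## Training

- **Pre-training** of the denoiser on paired low/high-resolution
  volumes: `L = gamma1 L_perc + gamma2 L_SRreg`, `gamma = (100, 1)`,
  Adam with learning rate 1e-5. `L_SRreg` is the sum of squared
  convolution-kernel entries (the printed "l2 norm" is read as the
  squared norm — standard weight decay). Toy pre-training sets augment
  the low/high pairs with repeated identity (high, high) pairs — the
  desk-scale surrogate for the data diversity that teaches `S` its
  fixed-point behavior on already-sharp inputs; heavier identity
  emphasis strengthens near-idempotence at the cost of super-resolution
  gain, and the validation experiments use the emphasis suited to the
  property under test.
- **End-to-end**: `L = eta1 L_perc + eta2 L_reg + eta3 L_mot`,
  `eta = (10, 1, 100)`, Adam at 1e-4 halved after a configurable epoch
  (500 in the full-scale schedule). `L_mot` is the self-supervised
  Charbonnier loss (`sqrt(|d|^2 + eps^2)`, `eps = 1e-3`) between the
  reference-bin image and the other bins' images warped back by the
  *inverse* of the predicted deformation — no ground-truth fields are
  used. Each epoch selects a fresh random patch from the central 50% of
  the x-axis per subject.
- **Gradient flow.** Backpropagation runs on a small reverse-mode
  autodiff over numpy arrays written for this package (dense N-D
  convolutions, pooling, warping with gradients to both image and
  field, a complex/2-channel bridge with the `dL/dRe + i dL/dIm`
  convention under which the VJP of any C-linear operator is its
  adjoint). The CG solve backpropagates by the converged-solve adjoint
  — the VJP of Step 1 with respect to its prior is
  `lam (E*E + lam I)^{-1}`, applied with the same fixed-iteration CG —
  the convention of the unrolled model-based learning lineage, keeping
  graph depth fixed. The perceptual loss reaches the denoiser through
  Step 2 and the CG steps; the motion network trains through the
  warping and scaling-and-squaring layers of `L_mot`, with the fields
  inside `E` treated as constants (fields are estimated once and frozen
  through the loop). The motion-only trainer adds a multi-scale variant
  of the Charbonnier loss (averages over 1x/2x/4x poolings) to widen
  the capture range for multi-voxel displacements — the standard
  multi-resolution registration device.

## Synthetic data

The phantom emulates the study's data generating process, not its
anatomy or contrast physics: ellipsoidal chambers, one curved bright
tube of 2-voxel diameter (so vessel sharpness is measurable without
segmentation), smooth complex phase; a pseudo-periodic breathing signal
(two sinusoids with seeded phase jitter; left-right amplitude 0.4x the
foot-head amplitude); per-bin deformations composed of the bin-mean
in-plane translation plus a non-rigid component built by exponentiating
a smooth random velocity (correlation length about a third of the grid)
scaled with respiratory depth at 0.3x the bulk amplitude — so ground-
truth invertibility holds by construction. Coil maps are smooth complex
Gaussians normalized to unit sum-of-squares. Navigators are 2x-coarser
coronal mean projections. Noise is i.i.d. complex Gaussian with SNR
defined as mean |signal| over noise standard deviation. Default study
conditions: 4 bins, 4 coils, 48 heartbeats, 2-voxel breathing amplitude,
SNR 30 for training subjects.

Two acquisition schemes mirror the prospective protocols: "4x4"
(approximately full variable-density sampling at 1.15x nominal
undersampling, 4x resolution reduction per phase-encode axis) and "2x2"
(4.5-fold undersampling, 2x reduction); both land near 18-fold overall
acceleration within the elliptical shutter.

What the phantom does **not** emulate: bSSFP/T2-prep contrast, intra-beat
cardiac motion, eddy currents, off-resonance, realistic coil geometry or
noise correlation, and through-plane respiratory motion of real
diaphragms. Passing tests therefore demonstrate the correctness of the
operators, the optimization, and the learning mechanics — not clinical
image quality.

## Experiment scales and numerical choices

Desk-scale experiment sizes (chosen so the full validation runs on one
CPU in minutes): motion-recovery training on 3 anatomies of 16x32x16
with fresh random in-plane translations up to +-3 voxels each epoch,
1500 epochs; end-to-end training on 8 subjects of 16x64x32 for 6 epochs
with 2-level, 4-channel networks and 16-voxel patches (discard 2,
overlap 2). Held-out motion recovery is scored as the mean over held-out
pairs of the per-pair maximum-axis error of the recovered mean
displacement, computed over the anatomy mask (background voxels carry no
registration signal and are excluded).

Numerical details: trilinear warps clamp at volume edges (zero-flux);
the fused normal operator collapses `D^T W^T W D` to a squared-weight
mask (exact, since readouts are unique per bin after consolidation);
zero-padding k-space to the next multiple of 16 rescales samples by
`sqrt(N'/N)` so voxel amplitudes are preserved under the unitary DFT;
the elliptical shutter never acquires k-space corners, so "exact"
recovery statements are with respect to the shutter-band-limited
reference. Vessel sharpness uses the inverse 20–80% edge-distance
convention capped at 100%, with the background estimated as the 10th
percentile of each perpendicular profile and the score averaged over
both sides and the first 4 cm of centerline. The SSIM scale factor is
found by bounded scalar search over [0.1, 10] (window 7, standard
constants, ROI bounding box); MSE and SSIM scales are optimized
separately, and the per-metric reading of "scaled separately" is a
documented choice.

## Known limitations

- The packaged feature extractor is a stand-in; perceptual-loss
  *values* are not comparable to those computed with a pretrained
  network, although the training mechanics are identical.
- Gradients of the reconstruction loss do not flow to the motion
  network through `E` (fields frozen in the loop); motion learning is
  driven by the self-supervised warp loss only.
- Patch-local warping clamps displacements at slab boundaries; large
  through-slab motion would alias between patches.
- CG backward uses the converged-solve approximation; at 5 iterations
  the Jacobian is approximate, which biases (slightly) but stabilizes
  training.
- Toy scales demonstrate mechanism, not clinical performance.
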