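# Methods

## Problem setting

Single-delay arterial spin labeling (ASL) yields a time series of
label/control difference volumes (ΔM) whose per-time-point SNR is very low;
clinical practice averages many repetitions. A learned denoiser can be
inserted between a *pre-averaging* step (average every N_av_pre raw time
points) and a *post-averaging* step (average the individually denoised
volumes), and the split N_av_pre × N_av_post of a fixed time budget, the
averaging scheme, the use of the calibration scan (M0) as a second input
channel, and the SNR match between training and inference all change the
end-to-end quality. This package implements that full pipeline — synthetic
cohorts, averaging operators, a volumetric encoder–decoder denoiser with
its training loop, image-quality metrics and the experiment harness — so the
design questions can be re-derived at desk (CPU) scale.

## Synthetic data model

Each subject is a `PerfusionPhantom`: an ellipsoidal brain (30–60 % of the
volume) whose perfusion field has a cortex-like high-intensity shell over a
lower core (shell/core mean contrast ≥ 2), multiplied by a smooth random
texture; a tissue (M0) field ≈ 1 inside the brain with a soft edge; and a
sparse vessel mask (≤ 1 % of in-mask voxels). Time point t of a scan is

    x_t = cbf · (1 + g_t + d_t) + a · p · (−1)^t + ε_t

with g_t ~ N(0, jitter²) a global multiplicative fluctuation (default
jitter 0.02 — perfusion is treated as temporally stable), d_t an optional
slow linear drift, `a·p·(−1)^t` an optional fast alternating subtraction
residual (a smooth spatial pattern that flips sign every time point, as an
imperfect label/control cancellation would), and ε_t i.i.d. voxelwise
Gaussian noise. M0 is the tissue field plus noise at one tenth of the ΔM
noise sigma. White Gaussian noise is the simplest model under which the
√N averaging premise of the whole study holds exactly.

Two SNR regimes are calibrated so single-time-point quality versus the
full average separates into two clusters, emulating the PASL (low) /
PCASL (high) split: noise sigma 0.45 and 0.15 against a shell signal of
~0.55 (single-time-point SSIM ≈ 0.35 vs ≈ 0.8). The default cohort mixes
one-third low-SNR and two-thirds high-SNR subjects.

What the generator does *not* emulate: spatially correlated (physiological)
noise, motion beyond additive transient stripe artifacts, multi-delay
kinetics, label/control pair physics, scanner-specific intensity scales.
Passing tests therefore demonstrate the pipeline's algebra and the
direction of the averaging/training effects under the stated noise model,
not performance on real scanner data.

## Averaging

`group_indices(n_t, n_av, scheme)` partitions 0..n_t−1: windowed groups are
consecutive blocks (equivalent to a shorter scan), interleaved groups take
every (n_t/n_av)-th time point (0-based, stride = number of groups — the
standard reading of color-cycled grouping diagrams; the rule is isolated in
one function so it can be swapped). Post-averaging merges consecutive
disjoint groups of denoised volumes; with N_av_pre · N_av_post < N_t
several *instances* remain and metrics are averaged instances → subject →
cohort. Ground truths: GT_100 % is the plain mean of all time points;
GT_50 %/GT_25 % use the first half/quarter, matching the use-the-first-N
convention for reduced scans.

Under white noise the two schemes are statistically indistinguishable (the
harness asserts this as a null control). A slow drift actually *favors*
interleaved averaging — each interleaved group spans the whole scan and
cancels the drift exactly as the ground-truth average does. The windowed
advantage reported for real data requires temporally *local* structure:
with the alternating subtraction residual, windowed groups (even counts of
consecutive points) cancel it while interleaved groups (same-parity
members) retain it in full. The scheme-comparison study condition therefore
uses `alt_residual_amp = 0.1`.

## Preprocessing

Volumes are normalized by one global subject factor so the mean intensity
of the subject's GT_100 % volume is 0.1 (the factor is recorded and
invertible; M0 gets its own factor). Resampling is corner-aligned trilinear
interpolation. The brain mask thresholds M0 at 0.2·max, applies one binary
closing and keeps the largest connected component; it is used *only* when
computing metrics — training and the loss see unmasked volumes, because
suppressing out-of-brain noise would favorably bias the evaluation.

## Denoiser

A 3D U-Net: per encoder level, `convs_per_block` × [3³ conv → batch norm →
leaky ReLU (slope 0.01)] then 2× max pooling, channel width doubling per
level from `init_channels`; a central block at the coarsest resolution with
an additive identity (residual) connection; a mirrored decoder using
stride-2 transposed convolutions, concatenation skips from the matching
encoder level, and a final linear 1×1×1 convolution. Defaults (64×64×32
input, 4 levels, 16 channels, 3 convs/block, dropout 0.05) give a 4×4×2×128
bottleneck. M0 enters as a second input channel when enabled. Batch-norm
order is conv → BN → activation; the bottleneck keeps the deepest encoder
width (init·2^(levels−1)).

No deep-learning framework is used: layers, batch-norm, dropout, the
optimizer (Adam) and the loss gradient are implemented directly on numpy
and verified against central finite differences in the test suite.

## Loss

    L = W · (1 − SSIM(pred, gt)) + (1 − W) · MSE(pred, gt),  W = 0.5

For evaluation, SSIM uses the standard 7×7×7 Gaussian-weighted window
(σ = 1.5, K1 = 0.01, K2 = 0.03, data range of the reference, computed
volumetrically). For the differentiable training loss the window is a
uniform 7³ box so the local statistics are box filters; with zero padding
the box filter is self-adjoint, which keeps the analytic SSIM gradient
exact (checked numerically). The loss data range is taken from the
ground-truth batch, so it is constant with respect to the prediction.

## Metrics

NMAE = in-mask mean |x − ref| / in-mask mean ref; with the mean-0.1
normalization it reads directly as a fractional perfusion error (this is
why the mean-reference normalizer is used rather than the data range,
which is available behind a flag). NME is the signed analogue and flags
systematic bias; |NME| ≤ NMAE always. PSNR uses the reference data range
per subject and reports a documented cap of 100 dB at zero MSE. SNR
dichotomization z-scores per-subject (mean SSIM, mean NMAE) single-time-
point features and runs 2-means with 10 restarts and a fixed seed; the
cluster with lower mean SSIM is "low".

## Training

Four-fold cross-validation splits subjects (not volumes) after shuffling;
10 % of each training set (rounded down, same shuffled order) is the
validation subset — per-subject splitting avoids leakage between roles.
Augmentation: all 8 in-plane flip/transpose symmetries deterministically,
plus random in-plane shifts (± 8 voxels) and rotations (± 45°, trilinear,
zero fill) in "full" mode; one seed produces one transform stream, so
paired input/GT/M0 stacks stay aligned. The full-scale schedule is Adam at
lr 0.002 halving after 15 epochs without validation improvement (floor
1e-5), max 300 epochs, early termination allowed after 240 when 20 epochs
bring no improvement, best-validation weights restored.

## Desk-scale presets and problem sizes

All shipped experiments run on one CPU. The documented desk cohort is 24
subjects (8 low-SNR) at 32×32×16; the test suite and the acceptance script
use a micro preset chosen to keep the full experiment grid in minutes:
12-subject cohorts (4 low-SNR) of 16×16×8 volumes with 32 time points, a
2-level/4-channel/2-convs-per-block model, and a 30–60-epoch schedule at
lr 0.01 (the higher rate compensates for the much smaller model and sample
count). The M0 ablation uses a slightly larger, lower-SNR-heavier cohort
(15 subjects, 6 low) so its stratified test set holds several subjects per
SNR group. Trend experiments repeat over ≥ 3 cohort seeds and compare
medians. In the averaging grid every N_av_train condition trains on the
same augmented sample budget (a capped base count expanded by the 8
deterministic symmetries), so grid cells differ by input SNR rather than
by how much data each condition's model happened to see.

## Design choices on open points

- Interleaved stride rule as above; isolated behind `group_indices`.
- One normalization factor per subject, derived from GT_100 %.
- Loss SSIM computed volumetrically (not per slice).
- PSNR data range = reference max − min per subject.
- Dropout is placed at the end of each conv block.
- Conv bias is kept even where batch norm follows (it is redundant there;
  harmless, and keeps the block definition uniform).
- Metric averaging order: instances → subject → cohort.
- Micro-scale inference uses the stored batch-norm running statistics
  (momentum 0.9), which converge within the shipped schedules.

## Known limitations

- A desk-scale model trained for tens of epochs has an identity-fidelity
  floor around 0.06 in-mask NMAE (with augmentation; ~0.1 without). Any
  comparison whose reference sits below that floor — e.g. denoising the
  nearly-clean GT_50 % of a *high*-SNR subject — cannot show improvement at
  this scale. The ground-truth-fraction generalizability experiment
  therefore reports pooled and SNR-stratified results, and its desk-scale
  claim is established in the low-SNR stratum, which is precisely the
  regime the experiment is about (a reduced-scan ground truth that is
  appreciably noisy). At full scale the floor is far below both strata.
- Absolute quality numbers at micro scale are far from those attainable
  with large cohorts and long GPU training; only directions of effects and
  exactly-computable structural quantities are asserted.
- No absolute CBF quantification is performed anywhere.
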