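"""Windowed vs interleaved pre-averaging on the same series.

Shows the grouping rules, the sqrt(N) noise reduction, and why the two
schemes diverge once the noise has fast temporally structured components
(an alternating label/control subtraction residual): windowed groups of
consecutive pairs cancel it, interleaved groups retain it.
"""

import numpy as np

from asldenoise import (AcquisitionParams, AveragingPlan, group_indices,
                        make_phantom, pre_average, simulate_series, ssim3d)

print("windowed   groups (n_t=8, n_av=2):",
      group_indices(8, 2, "windowed"))
print("interleaved groups (n_t=8, n_av=2):",
      group_indices(8, 2, "interleaved"))

phantom = make_phantom((32, 32, 16), seed=0)
scan = simulate_series(phantom, AcquisitionParams(
    n_timepoints=32, snr_regime="high", alt_residual_amp=0.1, seed=2))
gt = scan.gt(1.0)
mask = scan.brain_mask

for scheme in ("windowed", "interleaved"):
    plan = AveragingPlan(scheme=scheme, n_av_pre=16, n_timepoints=32)
    vols = pre_average(scan.series, plan)
    ssim = np.mean([ssim3d(np.where(mask, v, 0), np.where(mask, gt, 0))
                    for v in vols])
    resid = np.mean([(v - gt).std() for v in vols])
    print(f"{scheme:>11}: mean SSIM of the 2 pre-averaged volumes "
          f"{ssim:.3f}, residual std {resid:.4f}")

# With a fast alternating residual the windowed averages are clean while
# the interleaved averages keep the full residual amplitude, so windowed
# averaging scores higher against the full-average ground truth.
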