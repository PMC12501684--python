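"""Decompose pipeline quality gains into pre-averaging, denoising and
post-averaging contributions.

The three deltas telescope exactly to the total input-to-final gain,
mirroring the stage-wise accounting used to argue that averaging before
denoising is preferable to averaging after.
"""

from asldenoise import AveragingPlan, make_cohort, stepwise_improvement
from asldenoise.experiments import split_cohort, train_for_condition
from asldenoise.model import micro_config
from asldenoise.training import micro_schedule
from asldenoise.preprocess import normalize_scan

cohort = make_cohort(n_subjects=12, n_low=4, shape=(16, 16, 8),
                     n_timepoints=32, seed=0)
train, val, test = split_cohort(cohort, seed=0)
model = train_for_condition(train, val, n_av_train=4,
                            model_cfg=micro_config(),
                            schedule=micro_schedule(seed=0), seed=0)

scan = normalize_scan(test[0])
plan = AveragingPlan(n_av_pre=4, n_av_post=8, n_timepoints=32)
out = stepwise_improvement(scan, plan, model, scan.gt(1.0))

print(f"subject {scan.subject_id}, plan pre={plan.n_av_pre} "
      f"post={plan.n_av_post}")
for metric in ("ssim", "nmae"):
    d = out["deltas"][metric]
    print(f"  {metric}: pre-averaging {d['pre']:+.4f}, "
          f"denoising {d['dl']:+.4f}, post-averaging {d['post']:+.4f} "
          f"(total {d['total']:+.4f})")

# Positive SSIM deltas (negative NMAE deltas) are improvements; the sum of
# the three stage deltas equals the end-to-end change by construction.
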