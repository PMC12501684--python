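"""The consolidated desk-scale study: every experiment family at fixed
micro problem sizes, repeated over cohort seeds, summarized by medians.

This is the single source of truth for the CPU-scale study conditions
(cohort composition, volume size, schedules, sample budgets); the test
suite and the reproduction script both run it.  Problem sizes are chosen
so the full set of experiment families completes in minutes per seed on
one CPU; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import numpy as np

from .model import micro_config
from .synthetic import make_cohort
from .training import micro_schedule
from .experiments import (compare_schemes, run_gt_fraction, run_m0_ablation,
                          run_nav_grid, run_scan_time_sim, split_cohort,
                          train_for_condition)

__all__ = ["STUDY", "nav_grid_trial", "scheme_trial", "m0_trial",
           "gt_fraction_trial", "scan_time_trial", "median_over_seeds"]

#: Frozen desk-scale study conditions.
STUDY = {
    "n_subjects": 12,
    "n_low": 4,
    "shape": (16, 16, 8),
    "n_timepoints": 32,
    "grid_navs": (1, 4, 16),
    "scan_time_ntp": 8,
    "grid_epochs": 30,
    "grid_base_samples": 12,     # per-condition cap before 8x augmentation
    "m0_nav": 2,
    "m0_n_subjects": 15,
    "m0_n_low": 6,
    "m0_epochs": 50,
    "m0_samples": 96,
    "gt_fraction": 0.5,
    "gt_epochs": 60,
    "scheme_nav": 16,
    "scheme_epochs": 40,
    "alt_residual_amp": 0.1,
    "seeds": (1, 2, 3),
}


def _cohort(seed: int, **overrides):
    kw = dict(n_subjects=STUDY["n_subjects"], n_low=STUDY["n_low"],
              shape=STUDY["shape"], n_timepoints=STUDY["n_timepoints"],
              seed=seed)
    kw.update(overrides)
    return make_cohort(**kw)


def _schedule(seed: int, epochs: int):
    return micro_schedule(seed=seed, max_epochs=epochs,
                          early_stop_after=epochs)


def nav_grid_trial(seed: int) -> dict:
    """Matched-vs-mismatched N_av grid plus the scan-time simulation.

    Every N_av_train condition trains on the same augmented sample budget.
    Returns the number of grid rows won by the matched model (by median
    NMAE at the individually-denoised stage), the best post-averaged cell
    and the best (pre, post, train) triples per metric at the reduced
    scan-time budget.
    """
    cohort = _cohort(seed)
    train, val, test = split_cohort(cohort, seed=seed)
    sched = _schedule(seed, STUDY["grid_epochs"])
    navs = list(STUDY["grid_navs"])
    # the scan-time search additionally gets a model matched to the
    # reduced budget's maximal pre-averaging level
    train_navs = sorted(set(navs) | {STUDY["scan_time_ntp"]})
    models = {nav: train_for_condition(
        train, val, nav, model_cfg=micro_config(), schedule=sched,
        seed=seed, max_samples=STUDY["grid_base_samples"],
        augment_mode="deterministic") for nav in train_navs}
    grid = run_nav_grid(cohort, navs, navs, seed=seed,
                        models={n: models[n] for n in navs})

    den = grid[grid.stage == "denoised"]
    matched_wins = 0
    for nav_te in navs:
        sub = den[den.n_av_test == nav_te].set_index("n_av_train")
        if sub.nmae_median.idxmin() == nav_te:
            matched_wins += 1
    post = grid[grid.stage == "post_averaged"]
    best_post = post.loc[post.nmae_mean.idxmin()]

    table, best = run_scan_time_sim(test, [STUDY["scan_time_ntp"]], models)
    max_pre = max(int(p) for p in table.n_av_pre)
    pre_of_best = {r.metric: int(r.n_av_pre) for _, r in best.iterrows()}
    return {
        "matched_wins": matched_wins,
        "n_rows": len(navs),
        "grid": grid,
        "best_post_train": int(best_post.n_av_train),
        "best_post_test": int(best_post.n_av_test),
        "scan_time_table": table,
        "scan_time_best_pre": pre_of_best,
        "scan_time_max_pre_metrics": sum(
            v == max_pre for v in pre_of_best.values()),
    }


def scheme_trial(seed: int) -> dict:
    """Windowed vs interleaved with matched-scheme trained denoisers on a
    cohort carrying the fast alternating subtraction residual."""
    cohort = _cohort(seed, alt_residual_amp=STUDY["alt_residual_amp"])
    df = compare_schemes(cohort, [STUDY["scheme_nav"]],
                         model_cfg=micro_config(),
                         schedule=_schedule(seed, STUDY["scheme_epochs"]),
                         seed=seed, train=True)
    row = df[df.metric == "ssim"].iloc[0]
    return {"windowed_ssim": float(row.windowed_median),
            "interleaved_ssim": float(row.interleaved_median),
            "table": df}


def m0_trial(seed: int) -> dict:
    """With/without-M0 ablation stratified by the SNR dichotomization.

    Uses a slightly larger and lower-SNR-heavier cohort than the grid so
    the stratified test set holds enough subjects per SNR group.
    """
    cohort = _cohort(seed, n_subjects=STUDY["m0_n_subjects"],
                     n_low=STUDY["m0_n_low"])
    sched = _schedule(seed, STUDY["m0_epochs"])
    df = run_m0_ablation(cohort, n_av=STUDY["m0_nav"],
                         model_cfg=micro_config(), schedule=sched,
                         seed=seed, max_samples=STUDY["m0_samples"])
    out = {"table": df}
    for group in ("all", "low", "high"):
        sub = df[(df.group == group) & (df.metric == "ssim")]
        if len(sub):
            out[f"{group}_with_m0_ssim"] = float(
                sub.with_m0_median.iloc[0])
            out[f"{group}_without_m0_ssim"] = float(
                sub.without_m0_median.iloc[0])
    nme_row = df[(df.group == "all") & (df.metric == "nme")]
    out["abs_nme_ratio"] = float(nme_row.abs_nme_ratio.iloc[0])
    return out


def gt_fraction_trial(seed: int) -> dict:
    """Generalizability beyond a reduced (noisy) training ground truth."""
    cohort = _cohort(seed)
    res = run_gt_fraction(cohort, STUDY["gt_fraction"],
                          model_cfg=micro_config(),
                          schedule=_schedule(seed, STUDY["gt_epochs"]),
                          seed=seed, augment_mode="deterministic")
    return res["summary"]


def scan_time_trial(seed: int) -> dict:
    """Convenience wrapper exposing only the scan-time part of the grid."""
    return {k: v for k, v in nav_grid_trial(seed).items()
            if k.startswith("scan_time")}


def median_over_seeds(trials: list[dict], key: str) -> float:
    return float(np.median([t[key] for t in trials]))
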