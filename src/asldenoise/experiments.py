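"""Experiment orchestration: averaging grids, scheme comparison, ground-
truth-fraction generalizability, M0 ablation and scan-time simulation.

Every function takes an in-memory cohort (a list of ASLScan) plus explicit
model/schedule configs and a seed, and returns pandas DataFrames so results
are reproducible bit-for-bit given the same inputs.  Metric averaging
follows the instances -> subject -> cohort order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .averaging import AveragingPlan, post_average, pre_average
from .metrics import (LossParams, dichotomize_snr, nme, score_volume,
                      snr_features)
from .model import Denoiser3D, DenoiserConfig, IdentityDenoiser, micro_config
from .preprocess import normalize_scan
from .stats import paired_compare
from .synthetic import ASLScan
from .training import TrainSchedule, micro_schedule, train_denoiser

__all__ = ["split_cohort", "build_training_pairs", "train_for_condition",
           "evaluate_condition", "run_nav_grid", "compare_schemes",
           "run_gt_fraction", "run_m0_ablation", "run_scan_time_sim"]

METRICS = ("ssim", "psnr", "nmae")


def split_cohort(scans: list[ASLScan], seed: int = 0,
                 test_fraction: float = 1 / 3,
                 val_fraction: float = 0.15, stratify: bool = False):
    """Shuffle subjects and split into (train, val, test) scan lists.

    With ``stratify=True`` the split is performed within each SNR regime so
    that train and test keep the cohort's low/high mix.
    """
    if stratify:
        out = ([], [], [])
        for regime in ("low", "high"):
            group = [s for s in scans if s.regime == regime]
            if not group:
                continue
            parts = split_cohort(group, seed=seed,
                                 test_fraction=test_fraction,
                                 val_fraction=val_fraction)
            for acc, part in zip(out, parts):
                acc.extend(part)
        return out
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scans))
    n_test = max(1, int(round(test_fraction * len(scans))))
    n_val = max(1, int(round(val_fraction * (len(scans) - n_test))))
    test = [scans[i] for i in order[:n_test]]
    val = [scans[i] for i in order[n_test:n_test + n_val]]
    train = [scans[i] for i in order[n_test + n_val:]]
    return train, val, test


def _normalized(scans):
    return [normalize_scan(s) if s.norm_factor is None else s for s in scans]


def build_training_pairs(scans: list[ASLScan], n_av: int,
                         scheme: str = "windowed",
                         include_m0: bool = False,
                         gt_fraction: float = 1.0,
                         max_samples: int | None = None,
                         seed: int = 0,
                         augment_mode: str | None = None):
    """Assemble (inputs, targets[, M0]) stacks for one training condition.

    Inputs are the pre-averaged volumes of the first ``gt_fraction`` of each
    subject's time points; the target is that subject's temporal mean over
    the same window (GT_f), repeated for each of its inputs.  All volumes
    are subject-normalized.  ``augment_mode`` optionally expands the stacks
    geometrically (the same seed keeps input/target/M0 aligned).
    """
    X, Y, M = [], [], []
    for scan in _normalized(scans):
        n_eff = max(1, int(round(gt_fraction * scan.n_timepoints)))
        if n_eff % n_av:
            raise ValueError(
                f"n_av={n_av} does not divide the {n_eff} available "
                f"time points")
        plan = AveragingPlan(scheme=scheme, n_av_pre=n_av,
                             n_timepoints=n_eff)
        vols = pre_average(scan.series[:n_eff], plan)
        gt = scan.series[:n_eff].mean(axis=0)
        for v in vols:
            X.append(v)
            Y.append(gt)
            M.append(scan.m0)
    X, Y, M = np.stack(X), np.stack(Y), np.stack(M)
    if max_samples is not None and X.shape[0] > max_samples:
        keep = np.random.default_rng(seed).choice(
            X.shape[0], size=max_samples, replace=False)
        X, Y, M = X[keep], Y[keep], M[keep]
    if augment_mode is not None:
        from .training import augment
        X = augment(X, augment_mode, seed=seed)
        Y = augment(Y, augment_mode, seed=seed)
        M = augment(M, augment_mode, seed=seed)
    return (X, Y, M) if include_m0 else (X, Y)


def train_for_condition(train_scans, val_scans, n_av_train: int,
                        scheme: str = "windowed",
                        include_m0: bool = False,
                        model_cfg: DenoiserConfig | None = None,
                        schedule: TrainSchedule | None = None,
                        loss_params: LossParams = LossParams(),
                        gt_fraction: float = 1.0,
                        max_samples: int | None = 96,
                        seed: int = 0,
                        augment_mode: str | None = None) -> Denoiser3D:
    """Train one denoiser for one (N_av_train, scheme, M0) condition."""
    model_cfg = model_cfg or micro_config(
        input_shape=train_scans[0].series.shape[1:])
    if model_cfg.include_m0 != include_m0:
        from dataclasses import replace
        model_cfg = replace(model_cfg, include_m0=include_m0)
    schedule = schedule or micro_schedule(seed=seed)
    model = Denoiser3D(model_cfg)
    tr = build_training_pairs(train_scans, n_av_train, scheme, include_m0,
                              gt_fraction, max_samples, seed,
                              augment_mode=augment_mode)
    va = build_training_pairs(val_scans, n_av_train, scheme, include_m0,
                              gt_fraction, None, seed)
    model, _ = train_denoiser(model, tr, va, schedule, loss_params)
    return model


def _subject_stage_metrics(scan: ASLScan, model, n_av_test: int,
                           scheme: str, n_av_post: int | None = None):
    """Per-subject metrics at the denoised and post-averaged stages.

    Stage values are means over the available volumes/instances against the
    subject's GT_100%, brain-masked.
    """
    scan = _normalized([scan])[0]
    gt = scan.gt(1.0)
    mask = scan.brain_mask
    plan = AveragingPlan(scheme=scheme, n_av_pre=n_av_test,
                         n_timepoints=scan.n_timepoints)
    vols = pre_average(scan.series, plan)
    m0 = scan.m0 if getattr(model, "uses_m0", False) else None
    den = model.denoise(vols, m0=m0)
    if n_av_post is None:
        n_av_post = den.shape[0]  # full chain -> single grand instance
    post = post_average(den, n_av_post)

    def mean_scores(stack, stage):
        recs = [score_volume(v, gt, mask, stage=stage,
                             subject_id=scan.subject_id) for v in stack]
        return {m: float(np.mean([getattr(r, m) for r in recs]))
                for m in METRICS + ("nme",)}

    return {"denoised": mean_scores(den, "denoised"),
            "post_averaged": mean_scores(post, "post_averaged")}


def evaluate_condition(model, test_scans, n_av_test: int,
                       scheme: str = "windowed",
                       n_av_post: int | None = None) -> pd.DataFrame:
    """Evaluate a model on a test cohort at one N_av_test condition."""
    rows = []
    for scan in test_scans:
        stages = _subject_stage_metrics(scan, model, n_av_test, scheme,
                                        n_av_post)
        for stage, vals in stages.items():
            rows.append({"subject_id": scan.subject_id, "stage": stage,
                         "n_av_test": n_av_test, **vals})
    return pd.DataFrame(rows)


def run_nav_grid(cohort: list[ASLScan], nav_train_list, nav_test_list,
                 scheme: str = "windowed", include_m0: bool = False,
                 model_cfg: DenoiserConfig | None = None,
                 schedule: TrainSchedule | None = None,
                 loss_params: LossParams = LossParams(),
                 seed: int = 0, models: dict | None = None,
                 return_models: bool = False,
                 max_samples: int | None = 12,
                 augment_mode: str | None = "deterministic"):
    """Train one model per N_av_train and score every (train, test) cell.

    Returns a DataFrame with cohort-mean metrics per cell at the
    individually-denoised stage (n_av_post = 1) and after full-chain
    post-averaging, plus (optionally) the trained models keyed by
    N_av_train.  Passing ``models`` (e.g. {n: IdentityDenoiser()}) skips
    training.

    By default every N_av_train condition trains on the same budget — a
    capped base sample count expanded by deterministic augmentation — so
    that cells differ by their input SNR, not by how much data their model
    happened to see (N_av_pre = 1 yields 32x more raw volumes than 16).
    """
    train, val, test = split_cohort(cohort, seed=seed)
    if models is None:
        models = {}
        for nav in nav_train_list:
            models[nav] = train_for_condition(
                train, val, nav, scheme, include_m0, model_cfg, schedule,
                loss_params, seed=seed, max_samples=max_samples,
                augment_mode=augment_mode)
    rows = []
    for nav_tr in nav_train_list:
        for nav_te in nav_test_list:
            df = evaluate_condition(models[nav_tr], test, nav_te, scheme)
            for stage in ("denoised", "post_averaged"):
                sub = df[df.stage == stage]
                row = {"n_av_train": nav_tr, "n_av_test": nav_te,
                       "stage": stage}
                for m in METRICS + ("nme",):
                    row[f"{m}_mean"] = float(sub[m].mean())
                    row[f"{m}_median"] = float(sub[m].median())
                rows.append(row)
    grid = pd.DataFrame(rows)
    return (grid, models) if return_models else grid


def compare_schemes(cohort: list[ASLScan], nav_list,
                    model_cfg: DenoiserConfig | None = None,
                    schedule: TrainSchedule | None = None,
                    loss_params: LossParams = LossParams(),
                    seed: int = 0, train: bool = False,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Paired windowed-vs-interleaved comparison per N_av.

    With ``train=True`` a model is trained per scheme at the matched N_av
    (same split and seeds for both schemes) and the comparison is at the
    individually-denoised stage; otherwise the pre-averaged images are
    compared directly.  p-values carry Bonferroni correction across the
    N_av list.
    """
    n_cmp = len(nav_list)
    rows = []
    for nav in nav_list:
        per_scheme = {}
        for scheme in ("windowed", "interleaved"):
            if train:
                tr, va, te = split_cohort(cohort, seed=seed)
                model = train_for_condition(
                    tr, va, nav, scheme, False, model_cfg, schedule,
                    loss_params, seed=seed)
                df = evaluate_condition(model, te, nav, scheme)
                sub = df[df.stage == "denoised"]
                per_scheme[scheme] = sub.set_index("subject_id")
            else:
                recs = []
                for scan in _normalized(cohort):
                    gt = scan.gt(1.0)
                    plan = AveragingPlan(scheme=scheme, n_av_pre=nav,
                                         n_timepoints=scan.n_timepoints)
                    vols = pre_average(scan.series, plan)
                    scores = [score_volume(v, gt, scan.brain_mask,
                                           stage="pre_averaged")
                              for v in vols]
                    recs.append({
                        "subject_id": scan.subject_id,
                        **{m: float(np.mean([getattr(s, m) for s in scores]))
                           for m in METRICS}})
                per_scheme[scheme] = pd.DataFrame(recs).set_index(
                    "subject_id")
        w, i = per_scheme["windowed"], per_scheme["interleaved"]
        i = i.loc[w.index]
        for m in METRICS:
            res = paired_compare(w[m].to_numpy(), i[m].to_numpy(),
                                 alpha=alpha, n_comparisons=n_cmp)
            rows.append({
                "n_av": nav, "metric": m,
                "windowed_mean": float(w[m].mean()),
                "interleaved_mean": float(i[m].mean()),
                "windowed_median": float(w[m].median()),
                "interleaved_median": float(i[m].median()),
                "diff_mean": res["mean_diff"], "test": res["test"],
                "p_adj": res["p_adj"], "significant": res["significant"]})
    return pd.DataFrame(rows)


def run_gt_fraction(cohort: list[ASLScan], fraction: float = 0.5,
                    n_av_train: int | None = None,
                    model_cfg: DenoiserConfig | None = None,
                    schedule: TrainSchedule | None = None,
                    loss_params: LossParams = LossParams(),
                    seed: int = 0,
                    augment_mode: str | None = "deterministic") -> dict:
    """Generalizability test: train against a reduced ground truth GT_f.

    The model is trained on inputs pre-averaged from the first
    ``fraction`` of the time points with GT_f (their mean) as the target.
    At test time GT_f itself is the input and both it and its denoised
    version are scored against GT_100%: if denoising carries beyond its
    training target, the denoised GT_f lands closer to GT_100%.

    The summary is reported pooled and stratified by SNR regime: the
    effect is only visible where GT_f itself is appreciably noisy, i.e.
    in the low-SNR (PASL-like) stratum at small cohort scales.
    """
    train, val, test = split_cohort(cohort, seed=seed, stratify=True)
    n_t = cohort[0].n_timepoints
    n_eff = max(1, int(round(fraction * n_t)))
    if n_av_train is None:
        n_av_train = max(1, n_eff // 2)
    model = train_for_condition(train, val, n_av_train, "windowed", False,
                                model_cfg, schedule, loss_params,
                                gt_fraction=fraction, seed=seed,
                                augment_mode=augment_mode)
    rows = []
    for scan in _normalized(test):
        gt_full = scan.gt(1.0)
        gt_f = scan.gt(fraction)
        den = model.denoise(gt_f)
        mask = scan.brain_mask
        raw = score_volume(gt_f, gt_full, mask, stage="input",
                           subject_id=scan.subject_id)
        dn = score_volume(den, gt_full, mask, stage="denoised",
                          subject_id=scan.subject_id)
        rows.append({"subject_id": scan.subject_id, "regime": scan.regime,
                     **{f"raw_{m}": getattr(raw, m) for m in METRICS},
                     **{f"denoised_{m}": getattr(dn, m) for m in METRICS}})
    table = pd.DataFrame(rows)
    summary = {"fraction": fraction, "n_av_train": n_av_train}
    strata = {"all": table}
    for regime in ("low", "high"):
        sub = table[table.regime == regime]
        if len(sub):
            strata[regime] = sub
    for name, sub in strata.items():
        prefix = "" if name == "all" else f"{name}_"
        for m in METRICS:
            summary[f"{prefix}raw_{m}_median"] = float(
                sub[f"raw_{m}"].median())
            summary[f"{prefix}denoised_{m}_median"] = float(
                sub[f"denoised_{m}"].median())
        summary[f"{prefix}improved_nmae"] = bool(
            summary[f"{prefix}denoised_nmae_median"]
            < summary[f"{prefix}raw_nmae_median"])
    return {"table": table, "summary": summary, "model": model}


def run_m0_ablation(cohort: list[ASLScan], n_av: int = 2,
                    model_cfg: DenoiserConfig | None = None,
                    schedule: TrainSchedule | None = None,
                    loss_params: LossParams = LossParams(),
                    seed: int = 0, alpha: float = 0.05,
                    max_samples: int | None = 96,
                    augment_mode: str | None = None) -> pd.DataFrame:
    """Paired with/without-M0 comparison, stratified by SNR group.

    SNR groups come from 2-means dichotomization of single-time-point
    (SSIM, NMAE) features.  Alongside the three quality metrics, the signed
    NME bias is reported to check that conditioning on M0 does not inflate
    perfusion bias.
    """
    train, val, test = split_cohort(cohort, seed=seed, stratify=True)
    results = {}
    for include_m0 in (False, True):
        model = train_for_condition(train, val, n_av, "windowed",
                                    include_m0, model_cfg, schedule,
                                    loss_params, seed=seed,
                                    max_samples=max_samples,
                                    augment_mode=augment_mode)
        df = evaluate_condition(model, test, n_av, "windowed")
        results[include_m0] = df[df.stage == "denoised"].set_index(
            "subject_id")
    feats = snr_features(test)
    labels = dichotomize_snr(feats, seed=seed)
    label_map = {s.subject_id: lab for s, lab in zip(test, labels)}

    without, with_m0 = results[False], results[True]
    with_m0 = with_m0.loc[without.index]
    groups = {"all": list(without.index)}
    for lab in ("low", "high"):
        ids = [s for s in without.index if label_map[s] == lab]
        if len(ids) >= 2:
            groups[lab] = ids
    rows = []
    for gname, ids in groups.items():
        for m in METRICS + ("nme",):
            a = with_m0.loc[ids, m].to_numpy()
            b = without.loc[ids, m].to_numpy()
            res = (paired_compare(a, b, alpha=alpha, n_comparisons=4)
                   if len(ids) >= 3 else None)
            rows.append({
                "group": gname, "metric": m,
                "with_m0_median": float(np.median(a)),
                "without_m0_median": float(np.median(b)),
                "with_m0_mean": float(np.mean(a)),
                "without_m0_mean": float(np.mean(b)),
                "abs_nme_ratio": (float(np.abs(a).mean()
                                        / max(np.abs(b).mean(), 1e-12))
                                  if m == "nme" else np.nan),
                "p_adj": res["p_adj"] if res else np.nan,
                "test": res["test"] if res else ""})
    return pd.DataFrame(rows)


def _factor_pairs(n_tp: int):
    pairs = []
    p = 1
    while p <= n_tp:
        if n_tp % p == 0:
            pairs.append((p, n_tp // p))
        p *= 2
    return pairs


def run_scan_time_sim(test_scans: list[ASLScan], n_tp_list,
                      models: dict, scheme: str = "windowed"
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate reduced scan time: find the best (pre, post, train) triple.

    For each available N_tp, every power-of-two split N_av_pre * N_av_post
    = N_tp is chained over the full series (so 32/N_tp instances remain for
    metric averaging) with every candidate model.  Returns the full table
    and the best triple per (N_tp, metric).
    """
    rows = []
    for n_tp in n_tp_list:
        for pre, post in _factor_pairs(n_tp):
            for nav_train, model in models.items():
                per_subject = []
                for scan in _normalized(test_scans):
                    gt = scan.gt(1.0)
                    mask = scan.brain_mask
                    plan = AveragingPlan(scheme=scheme, n_av_pre=pre,
                                         n_timepoints=scan.n_timepoints)
                    vols = pre_average(scan.series, plan)
                    m0 = scan.m0 if getattr(model, "uses_m0", False) \
                        else None
                    den = model.denoise(vols, m0=m0)
                    inst = post_average(den, post)
                    scores = [score_volume(v, gt, mask,
                                           stage="post_averaged")
                              for v in inst]
                    per_subject.append(
                        {m: float(np.mean([getattr(s, m) for s in scores]))
                         for m in METRICS})
                dfs = pd.DataFrame(per_subject)
                rows.append({"n_tp": n_tp, "n_av_pre": pre,
                             "n_av_post": post, "n_av_train": nav_train,
                             "n_instances": scan.n_timepoints // n_tp,
                             **{f"{m}_mean": float(dfs[m].mean())
                                for m in METRICS},
                             **{f"{m}_median": float(dfs[m].median())
                                for m in METRICS}})
    table = pd.DataFrame(rows)
    best_rows = []
    for n_tp in n_tp_list:
        sub = table[table.n_tp == n_tp]
        for m in METRICS:
            col = f"{m}_mean"
            idx = sub[col].idxmin() if m == "nmae" else sub[col].idxmax()
            r = sub.loc[idx]
            best_rows.append({"n_tp": n_tp, "metric": m,
                              "n_av_pre": int(r.n_av_pre),
                              "n_av_post": int(r.n_av_post),
                              "n_av_train": r.n_av_train,
                              "value": float(r[col])})
    return table, pd.DataFrame(best_rows)
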