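"""Image-quality metrics, the combined training loss, SNR dichotomization
and the stage-wise improvement decomposition.

All full-reference metrics score a volume against the subject's
temporal-mean ground truth.  NMAE is in-mask mean absolute error divided by
the in-mask mean of the reference, so with mean-normalized volumes it reads
directly as a fractional perfusion error; NME is its signed counterpart and
flags systematic bias.  SSIM uses a 7x7x7 Gaussian-weighted window
(sigma = 1.5, K1 = 0.01, K2 = 0.03) with the data range taken from the
reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.metrics import structural_similarity
from sklearn.cluster import KMeans

from .averaging import AveragingPlan, post_average, pre_average

__all__ = [
    "MetricRecord",
    "LossParams",
    "ssim3d",
    "psnr",
    "nmae",
    "nme",
    "combined_loss",
    "score_volume",
    "dichotomize_snr",
    "snr_features",
    "stepwise_improvement",
]

#: Reported PSNR when the two volumes are identical (MSE = 0).
PSNR_CAP_DB = 100.0

METRIC_NAMES = ("ssim", "psnr", "nmae")
STAGES = ("input", "pre_averaged", "denoised", "post_averaged")


@dataclass
class MetricRecord:
    """Per-volume quality scores against a stated reference."""

    ssim: float
    psnr: float
    nmae: float
    nme: float
    stage: Literal["input", "pre_averaged", "denoised", "post_averaged"]
    subject_id: str = ""
    n_av_train: int | None = None
    n_av_test: int | None = None


@dataclass
class LossParams:
    """Weight of the SSIM term in the combined training loss."""

    w: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("loss weight w must lie in [0, 1]")


def _data_range(ref: np.ndarray) -> float:
    r = float(ref.max() - ref.min())
    return r if r > 0 else 1.0  # two constant volumes: any C > 0 gives SSIM 1


def ssim3d(a: np.ndarray, b: np.ndarray,
           data_range: float | None = None) -> float:
    """Mean local structural similarity over a sliding 3D window.

    ``b`` is the reference; unless given, the data range is b's max - min.
    """
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    if data_range is None:
        data_range = _data_range(b)
    return float(structural_similarity(
        a, b, data_range=data_range, win_size=7,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        K1=0.01, K2=0.03))


def psnr(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB, capped at PSNR_CAP_DB when MSE = 0."""
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(data_range ** 2 / mse))


def _masked(x: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.asarray(x, float).ravel()
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return np.asarray(x, float)[mask]


def nmae(x: np.ndarray, ref: np.ndarray,
         mask: np.ndarray | None = None,
         normalizer: str = "mean") -> float:
    """In-mask mean |x - ref| divided by the in-mask mean of ref.

    With the mean-reference normalizer (default) and mean-normalized
    volumes, the value reads as a fractional perfusion error.  The
    alternative ``normalizer="range"`` divides by the reference data range
    instead.
    """
    xv, rv = _masked(x, mask), _masked(ref, mask)
    if normalizer == "mean":
        denom = float(rv.mean())
    elif normalizer == "range":
        denom = float(rv.max() - rv.min())
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if denom == 0.0:
        raise ValueError("reference normalizer is zero inside the mask")
    return float(np.abs(xv - rv).mean() / denom)


def nme(x: np.ndarray, ref: np.ndarray,
        mask: np.ndarray | None = None) -> float:
    """Signed in-mask mean (x - ref) divided by the in-mask mean of ref."""
    xv, rv = _masked(x, mask), _masked(ref, mask)
    denom = float(rv.mean())
    if denom == 0.0:
        raise ValueError("reference mean is zero inside the mask")
    return float((xv - rv).mean() / denom)


def combined_loss(pred: np.ndarray, gt: np.ndarray,
                  params: LossParams = LossParams()) -> float:
    """Scalar training objective W*(1 - SSIM) + (1 - W)*MSE, batch-averaged.

    This is the evaluation-side scalar; the trainer uses the differentiable
    twin in :mod:`asldenoise.nn.loss` (uniform instead of Gaussian window).
    """
    pred = np.asarray(pred, float)
    gt = np.asarray(gt, float)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must share a shape")
    if pred.ndim == 3:
        pred, gt = pred[None], gt[None]
    vals = []
    for p, g in zip(pred, gt):
        s = ssim3d(p, g)
        mse = float(np.mean((p - g) ** 2))
        vals.append(params.w * (1.0 - s) + (1.0 - params.w) * mse)
    return float(np.mean(vals))


def score_volume(x: np.ndarray, ref: np.ndarray,
                 mask: np.ndarray | None = None,
                 stage: str = "input", subject_id: str = "",
                 **ids) -> MetricRecord:
    """Compute all four metrics of one volume against a reference.

    SSIM/PSNR are computed on the masked arrays restored into a zeroed
    volume only if a mask is given — following the convention that metrics
    are brain-masked at the analysis stage.
    """
    if mask is not None:
        mask = np.asarray(mask, bool)
        xm = np.where(mask, x, 0.0)
        rm = np.where(mask, ref, 0.0)
    else:
        xm, rm = x, ref
    dr = _data_range(rm)
    return MetricRecord(
        ssim=ssim3d(xm, rm, data_range=dr),
        psnr=psnr(xm, rm, data_range=dr),
        nmae=nmae(x, ref, mask),
        nme=nme(x, ref, mask),
        stage=stage, subject_id=subject_id, **ids)


def snr_features(scans, masks=None) -> np.ndarray:
    """Per-subject (mean SSIM, mean NMAE) of single time points vs GT_100%."""
    feats = []
    for i, scan in enumerate(scans):
        gt = scan.gt(1.0)
        mask = scan.brain_mask if masks is None else masks[i]
        dr = _data_range(np.where(mask, gt, 0.0))
        ss, nm = [], []
        for t in range(scan.n_timepoints):
            vol = scan.series[t]
            ss.append(ssim3d(np.where(mask, vol, 0.0),
                             np.where(mask, gt, 0.0), data_range=dr))
            nm.append(nmae(vol, gt, mask))
        feats.append((float(np.mean(ss)), float(np.mean(nm))))
    return np.asarray(feats)


def dichotomize_snr(features: Sequence, seed: int = 0) -> np.ndarray:
    """Split subjects into low/high-SNR groups by 2-means clustering.

    ``features`` is an (n, 2) array of per-subject (mean SSIM, mean NMAE) at
    the single-time-point level.  Features are z-scored, k-means is run with
    10 restarts, and the cluster with the lower mean SSIM is labeled "low".
    """
    feats = np.asarray(features, float)
    if feats.ndim != 2 or feats.shape[1] != 2 or feats.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) feature array")
    std = feats.std(axis=0)
    if np.all(std == 0):
        raise ValueError("degenerate features: all subjects identical")
    z = (feats - feats.mean(axis=0)) / np.where(std > 0, std, 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    lab = km.labels_
    mean_ssim = [feats[lab == c, 0].mean() for c in (0, 1)]
    low = int(np.argmin(mean_ssim))
    return np.where(lab == low, "low", "high")


def stepwise_improvement(scan, plan: AveragingPlan, model,
                         gt: np.ndarray,
                         mask: np.ndarray | None = None) -> dict:
    """Decompose the quality gain of the full pipeline into per-stage deltas.

    For each metric m: delta_pre = m(pre-averaged) - m(single time points),
    delta_dl = m(denoised) - m(pre-averaged), delta_post = m(post-averaged)
    - m(denoised); stage values are averaged across time points / volumes /
    instances first.  The three deltas telescope exactly to
    m(final) - m(input).
    """
    if mask is None:
        mask = scan.brain_mask
    m0 = scan.m0 if getattr(model, "uses_m0", False) else None

    pre = pre_average(scan.series, plan)
    den = model.denoise(pre, m0=m0)
    post = post_average(den, plan.n_av_post)

    def stage_mean(stack):
        recs = [score_volume(v, gt, mask) for v in stack]
        return {k: float(np.mean([getattr(r, k) for r in recs]))
                for k in METRIC_NAMES + ("nme",)}

    vals = {
        "input": stage_mean(scan.series),
        "pre_averaged": stage_mean(pre),
        "denoised": stage_mean(den),
        "post_averaged": stage_mean(post),
    }
    out = {"stages": vals, "deltas": {}}
    for k in METRIC_NAMES + ("nme",):
        out["deltas"][k] = {
            "pre": vals["pre_averaged"][k] - vals["input"][k],
            "dl": vals["denoised"][k] - vals["pre_averaged"][k],
            "post": vals["post_averaged"][k] - vals["denoised"][k],
            "total": vals["post_averaged"][k] - vals["input"][k],
        }
    return out
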