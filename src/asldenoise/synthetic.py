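"""Synthetic single-delay ASL cohort generator.

Arterial spin labeling (ASL) measures perfusion from label/control
difference images (dM).  A single-delay scan is a stack of ``n_timepoints``
difference volumes plus one calibration (M0) volume.  The generator builds a
perfusion phantom per subject and simulates a temporally stable perfusion
signal with additive Gaussian noise, a small multiplicative global
fluctuation, and optional structured components:

* a slow linear intensity drift across the scan,
* a fast alternating (pair-to-pair) subtraction residual — an imperfect
  label/control cancellation that flips sign at every time point,
* transient motion-like stripe artifacts on a small subset of time points,
* a persistent intravascular hyperintensity on vessel voxels (which is real
  ASL signal, not noise).

Two SNR regimes are provided: ``low`` mimics pulsed-ASL (PASL) noise levels
and ``high`` mimics pseudo-continuous ASL (PCASL).  The regime noise sigmas
are package defaults chosen so that single-time-point image quality versus
the temporal-mean reference separates into two clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "PerfusionPhantom",
    "AcquisitionParams",
    "ASLScan",
    "REGIME_SIGMA",
    "make_phantom",
    "simulate_series",
    "inject_artifacts",
    "make_cohort",
    "SimulationConfig",
]

#: Default additive-noise standard deviations per SNR regime, in the same
#: arbitrary units as the phantom perfusion field (shell signal ~0.55).
#: ``high`` is PCASL-like, ``low`` is PASL-like.
REGIME_SIGMA = {"high": 0.15, "low": 0.45}

#: M0 volumes in practice have far higher SNR than the difference images;
#: the M0 noise std is fixed at noise_sigma / 10.
M0_NOISE_FRACTION = 0.1


@dataclass
class PerfusionPhantom:
    """Ground-truth perfusion anatomy for one synthetic subject.

    ``cbf_map`` is the noiseless perfusion field (arbitrary units),
    ``tissue_map`` the noiseless proton-density (M0) field, ``brain_mask``
    the true brain support and ``vessel_mask`` a sparse set of intravascular
    loci.  ``geometry`` records the ellipsoid (center, semi-axes) used for
    construction so that region masks (cortex-like shell vs core) can be
    recomputed.
    """

    cbf_map: np.ndarray
    tissue_map: np.ndarray
    brain_mask: np.ndarray
    vessel_mask: np.ndarray
    geometry: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.cbf_map.shape

    def region_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (shell_mask, core_mask) from the stored ellipsoid geometry."""
        rho = _ellipsoid_rho(self.shape, self.geometry["center"],
                             self.geometry["semi_axes"])
        core = rho < 0.6
        shell = (rho >= 0.7) & (rho <= 1.0)
        return shell, core


@dataclass
class AcquisitionParams:
    """Simulation parameters for one scan.

    noise_sigma
        Std of the i.i.d. voxelwise Gaussian noise added to every time
        point, in the units of the perfusion field.  ``None`` selects the
        regime default from :data:`REGIME_SIGMA`.
    temporal_jitter
        Std of the per-time-point multiplicative global fluctuation g_t;
        time point t carries signal ``cbf * (1 + g_t)``.
    temporal_drift
        Peak-to-peak amplitude of a slow linear multiplicative drift across
        the scan (0 disables).
    alt_residual_amp
        Amplitude of the fast alternating subtraction residual: a smooth
        spatial pattern times (-1)**t (0 disables).
    artifact_rate
        Per-time-point probability of a transient motion-like artifact,
        consumed by :func:`inject_artifacts`.
    """

    n_timepoints: int = 32
    noise_sigma: float | None = None
    snr_regime: Literal["low", "high"] = "high"
    temporal_jitter: float = 0.02
    temporal_drift: float = 0.0
    alt_residual_amp: float = 0.0
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.snr_regime not in ("low", "high"):
            raise ValueError(f"unknown snr_regime {self.snr_regime!r}")

    @property
    def sigma(self) -> float:
        return (REGIME_SIGMA[self.snr_regime]
                if self.noise_sigma is None else self.noise_sigma)


@dataclass
class ASLScan:
    """One subject's simulated (or loaded) single-delay ASL scan.

    ``series`` has shape (n_timepoints, x, y, z); ``m0`` and ``brain_mask``
    share the spatial shape.  ``norm_factor`` is the subject-level scaling
    that has been applied (``None`` if unnormalized).  ``meta`` carries the
    phantom, acquisition parameters and artifact bookkeeping.
    """

    series: np.ndarray
    m0: np.ndarray
    brain_mask: np.ndarray
    regime: str = "high"
    subject_id: str = "sub-000"
    norm_factor: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.series.ndim != 4:
            raise ValueError("series must be 4D (t, x, y, z)")
        if self.series.shape[1:] != self.m0.shape:
            raise ValueError("series and m0 spatial shapes differ")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    def gt(self, fraction: float = 1.0) -> np.ndarray:
        """Temporal-mean reference over the first ``fraction`` of time points.

        fraction=1.0 is the full-average ground truth; 0.5 / 0.25 give the
        half- and quarter-scan references used in the generalizability
        experiments.
        """
        n = max(1, int(round(fraction * self.n_timepoints)))
        return self.series[:n].mean(axis=0)


def _ellipsoid_rho(shape, center, semi_axes):
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                        indexing="ij")
    rho2 = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        rho2 += ((g - c) / a) ** 2
    return np.sqrt(rho2)


def make_phantom(shape: tuple[int, int, int], seed: int) -> PerfusionPhantom:
    """Build a deterministic perfusion phantom.

    The brain is an ellipsoid occupying 30-60% of the volume.  The perfusion
    field has a cortex-like high-intensity shell over a lower-intensity core
    (shell/core mean contrast >= 2) modulated by a smooth random texture; the
    tissue field is close to uniform inside the brain and everywhere >= the
    perfusion field.  Both fields decay smoothly just outside the mask
    (enlarged support).  A sparse vessel mask (<= 1% of in-mask voxels)
    marks intravascular loci.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 8 for n in shape):
        raise ValueError("each phantom dimension must be >= 8")
    rng = np.random.default_rng(seed)

    center = [n / 2 + rng.uniform(-0.03, 0.03) * n for n in shape]
    semi_axes = [rng.uniform(0.42, 0.48) * n for n in shape]
    rho = _ellipsoid_rho(shape, center, semi_axes)
    brain = rho <= 1.0

    # radial profile: core plateau 0.2, shell 0.55, smooth falloff at edge;
    # blur scales with volume size so the thin shell survives small grids
    profile = np.where(rho < 0.65, 0.20,
                       np.where(rho <= 1.0, 0.55, 0.0))
    blur = max(0.3, 0.012 * min(shape))
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5)
    texture = 1.0 + 0.12 * texture / max(texture.std(), 1e-12)
    cbf = ndimage.gaussian_filter(profile, blur) * texture
    cbf = np.clip(cbf, 0.0, None)

    # tissue: ~1 inside the brain with a soft edge of ~0.12 in normalized
    # ellipsoid-radius units, so the M0-threshold mask tracks the true mask
    t = np.clip((1.06 - rho) / 0.12, 0.0, 1.0)
    tissue = t * t * (3.0 - 2.0 * t)
    tissue *= 1.0 + 0.05 * ndimage.gaussian_filter(
        rng.standard_normal(shape), 2.0)
    tissue = np.clip(tissue, 0.0, None)

    # enlarged support: zero both fields outside a slightly dilated brain
    support = ndimage.binary_dilation(brain, iterations=2)
    cbf[~support] = 0.0
    tissue[~support] = 0.0
    tissue = np.maximum(tissue, cbf)

    # sparse vessel loci: a few seeds inside the brain, dilated once
    n_in = int(brain.sum())
    vessel = np.zeros(shape, dtype=bool)
    in_idx = np.flatnonzero(brain.ravel())
    n_seeds = max(1, n_in // 800)
    chosen = rng.choice(in_idx, size=n_seeds, replace=False)
    vessel.ravel()[chosen] = True
    vessel = ndimage.binary_dilation(vessel) & brain
    if vessel.sum() > 0.01 * n_in:  # enforce sparsity cap
        keep = np.flatnonzero(vessel.ravel())[: int(0.01 * n_in)]
        vessel = np.zeros(shape, dtype=bool)
        vessel.ravel()[keep] = True

    return PerfusionPhantom(
        cbf_map=cbf, tissue_map=tissue, brain_mask=brain,
        vessel_mask=vessel,
        geometry={"center": center, "semi_axes": semi_axes},
    )


def simulate_series(phantom: PerfusionPhantom,
                    params: AcquisitionParams) -> ASLScan:
    """Simulate a noisy difference-image time series from a phantom.

    Time point t is ``cbf * (1 + g_t + d_t) + a * p * (-1)**t + eps_t`` with
    g_t a global Gaussian jitter, d_t the optional linear drift, p a smooth
    zero-mean spatial pattern for the alternating residual and eps_t i.i.d.
    voxelwise Gaussian noise.  The temporal mean converges to the perfusion
    field as the number of time points grows.  M0 is the tissue field plus
    low-amplitude noise.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    T = params.n_timepoints
    sigma = params.sigma
    shape = phantom.shape

    g = (rng.normal(0.0, params.temporal_jitter, size=T)
         if params.temporal_jitter > 0 else np.zeros(T))
    if params.temporal_drift > 0 and T > 1:
        drift = params.temporal_drift * (np.arange(T) / (T - 1) - 0.5)
    else:
        drift = np.zeros(T)

    if params.alt_residual_amp > 0:
        pat = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
        pat = pat / max(np.abs(pat).std(), 1e-12)
        support = phantom.tissue_map > 0
        pat = params.alt_residual_amp * pat * support
    else:
        pat = np.zeros(shape)

    series = np.empty((T,) + shape, dtype=np.float64)
    signs = (-1.0) ** np.arange(T)
    for t in range(T):
        vol = phantom.cbf_map * (1.0 + g[t] + drift[t]) + signs[t] * pat
        if sigma > 0:
            vol = vol + rng.normal(0.0, sigma, size=shape)
        series[t] = vol

    m0 = phantom.tissue_map.copy()
    if sigma > 0:
        m0 = m0 + rng.normal(0.0, M0_NOISE_FRACTION * sigma, size=shape)

    return ASLScan(
        series=series, m0=m0, brain_mask=phantom.brain_mask.copy(),
        regime=params.snr_regime, subject_id=f"sub-{params.seed:03d}",
        meta={"phantom": phantom, "params": params},
    )


def inject_artifacts(scan: ASLScan,
                     kind: Literal["transient_motion", "intravascular"],
                     seed: int) -> ASLScan:
    """Return a copy of the scan with one artifact family added.

    ``transient_motion`` adds a high-amplitude stripe/ghost pattern to a
    random subset of at most 20% of the time points (rate taken from the
    scan's acquisition parameters).  ``intravascular`` adds a persistent
    hyperintensity on the vessel voxels of ALL time points — this is real
    arterial signal that a faithful denoiser must preserve, so it raises the
    temporal mean on those voxels without touching the temporal std.
    Bookkeeping of affected time points / voxels goes into ``meta``.
    """
    rng = np.random.default_rng(seed)
    series = scan.series.copy()
    meta = dict(scan.meta)
    params: AcquisitionParams | None = meta.get("params")
    T = scan.n_timepoints
    shape = scan.series.shape[1:]

    if kind == "transient_motion":
        rate = params.artifact_rate if params is not None else 0.1
        flagged = np.flatnonzero(rng.random(T) < rate)
        cap = max(1, int(np.floor(0.2 * T))) if rate > 0 else 0
        flagged = flagged[:cap]
        if flagged.size:
            x = np.arange(shape[0], dtype=float)
            stripes = np.sin(2 * np.pi * x / max(4, shape[0] // 4))
            pattern = np.broadcast_to(
                stripes[:, None, None], shape).copy()
            amp = 1.5 * max(scan.series.std(), 1e-12)
            for t in flagged:
                phase = rng.integers(0, shape[0])
                series[t] = series[t] + amp * np.roll(pattern, phase, axis=0)
        meta["artifacts"] = {"kind": kind, "timepoints": flagged.tolist()}
    elif kind == "intravascular":
        vessel = meta.get("vessel_mask")
        if vessel is None and meta.get("phantom") is not None:
            vessel = meta["phantom"].vessel_mask
        if vessel is None:
            raise ValueError("intravascular artifacts need a vessel mask")
        amp = 3.0 * max(scan.series.mean(), 1e-12)
        series[:, vessel] += amp
        meta["artifacts"] = {"kind": kind,
                             "n_voxels": int(vessel.sum()), "amp": amp}
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")

    return replace(scan, series=series, meta=meta)


def make_cohort(n_subjects: int = 24, n_low: int = 8,
                shape: tuple[int, int, int] = (32, 32, 16),
                n_timepoints: int = 32, seed: int = 0,
                temporal_jitter: float = 0.02,
                temporal_drift: float = 0.0,
                alt_residual_amp: float = 0.0) -> list[ASLScan]:
    """Simulate a cohort of subjects mixing the two SNR regimes.

    The first ``n_low`` subjects are drawn from the low-SNR (PASL-like)
    regime, the rest from the high-SNR (PCASL-like) regime.  Each subject
    gets its own phantom and noise realization derived deterministically
    from ``seed``.
    """
    if not 0 <= n_low <= n_subjects:
        raise ValueError("need 0 <= n_low <= n_subjects")
    scans = []
    for i in range(n_subjects):
        regime = "low" if i < n_low else "high"
        phantom = make_phantom(shape, seed=seed * 1_000 + i)
        params = AcquisitionParams(
            n_timepoints=n_timepoints, snr_regime=regime,
            temporal_jitter=temporal_jitter,
            temporal_drift=temporal_drift,
            alt_residual_amp=alt_residual_amp,
            seed=seed * 1_000 + i)
        scan = simulate_series(phantom, params)
        scan.subject_id = f"sub-{i:03d}"
        scans.append(scan)
    return scans


def desk_cohort(seed: int = 0, **kwargs) -> list[ASLScan]:
    """The default desk-scale study cohort: 24 subjects (8 low-SNR PASL-like,
    16 high-SNR PCASL-like), 32x32x16 volumes, 32 time points."""
    defaults = dict(n_subjects=24, n_low=8, shape=(32, 32, 16),
                    n_timepoints=32, seed=seed)
    defaults.update(kwargs)
    return make_cohort(**defaults)


@dataclass
class SimulationConfig:
    """YAML/JSON-loadable simulation settings."""

    shape: tuple[int, int, int] = (64, 64, 32)
    n_timepoints: int = 32
    n_subjects: int = 24
    n_low: int = 8
    regime_sigmas: dict = field(
        default_factory=lambda: dict(REGIME_SIGMA))
    temporal_jitter: float = 0.02
    temporal_drift: float = 0.0
    alt_residual_amp: float = 0.0
    artifact_rate: float = 0.0
    voxel_size: tuple[float, float, float] = (3.8, 3.8, 3.8)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown simulation config key {k!r}")
            if isinstance(getattr(cfg, k), tuple):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg

    def cohort(self) -> list[ASLScan]:
        scans = []
        for i in range(self.n_subjects):
            regime = "low" if i < self.n_low else "high"
            phantom = make_phantom(self.shape, seed=self.seed * 1_000 + i)
            params = AcquisitionParams(
                n_timepoints=self.n_timepoints,
                noise_sigma=self.regime_sigmas[regime],
                snr_regime=regime,
                temporal_jitter=self.temporal_jitter,
                temporal_drift=self.temporal_drift,
                alt_residual_amp=self.alt_residual_amp,
                artifact_rate=self.artifact_rate,
                seed=self.seed * 1_000 + i)
            scan = simulate_series(phantom, params)
            scan.subject_id = f"sub-{i:03d}"
            scans.append(scan)
        return scans
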