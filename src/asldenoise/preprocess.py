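"""Intensity normalization, resampling and brain masking.

Normalization scales each subject's volumes by one global factor so that the
mean intensity of the reference volume is 0.1; the factor is recorded so
original intensities (and hence quantification) can be recovered.  The brain
mask is used only when computing image-quality metrics — training and the
loss always see unmasked volumes, since suppressing out-of-brain noise would
favorably bias the evaluation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .synthetic import ASLScan

__all__ = [
    "MaskError",
    "normalize_volume",
    "normalize_scan",
    "resample_trilinear",
    "brain_mask_from_m0",
]

TARGET_MEAN = 0.1


class MaskError(RuntimeError):
    """Raised when brain-mask extraction fails (e.g. empty threshold set)."""


def normalize_volume(volume: np.ndarray,
                     target_mean: float = TARGET_MEAN
                     ) -> tuple[np.ndarray, float]:
    """Scale a volume so its mean intensity equals ``target_mean``.

    Returns ``(scaled, factor)`` with ``scaled = volume * factor``; dividing
    by the factor recovers the original intensities exactly.
    """
    mean = float(np.mean(volume))
    if abs(mean) < 1e-300 or not np.isfinite(mean):
        raise ValueError("cannot normalize a volume with zero mean intensity")
    factor = target_mean / mean
    return volume * factor, factor


def normalize_scan(scan: ASLScan,
                   target_mean: float = TARGET_MEAN) -> ASLScan:
    """Apply subject-level normalization to a whole scan.

    One global factor is derived from the subject's full temporal-mean
    volume and applied to every time point, preserving relative perfusion.
    M0 is normalized independently by its own factor (its intensity scale is
    unrelated to the difference images).
    """
    _, factor = normalize_volume(scan.gt(1.0), target_mean)
    m0_scaled, m0_factor = normalize_volume(scan.m0, target_mean)
    meta = dict(scan.meta)
    meta["m0_norm_factor"] = m0_factor
    return replace(scan, series=scan.series * factor, m0=m0_scaled,
                   norm_factor=factor, meta=meta)


def resample_trilinear(volume: np.ndarray,
                       target_shape: tuple[int, int, int]) -> np.ndarray:
    """Resample a 3D volume to ``target_shape`` by trilinear interpolation.

    The grid maps the source extent onto the target extent with corner
    alignment: output index i maps to source coordinate
    i * (n_src - 1) / (n_tgt - 1).
    """
    target_shape = tuple(int(n) for n in target_shape)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    if any(n < 1 for n in target_shape):
        raise ValueError("target shape dimensions must be >= 1")
    if any(n < 2 for n in volume.shape):
        raise ValueError("source dimensions must be >= 2")
    if target_shape == volume.shape:
        return volume.copy()
    axes = [np.linspace(0.0, s - 1.0, t) if t > 1 else np.array([(s - 1) / 2])
            for s, t in zip(volume.shape, target_shape)]
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(volume, coords, order=1, mode="nearest")


def brain_mask_from_m0(m0: np.ndarray, fraction: float = 0.2) -> np.ndarray:
    """Estimate the brain mask from an M0 volume.

    Thresholds at ``fraction * max(m0)``, applies one binary-closing pass and
    keeps the largest connected component.  Intended for the analysis stage
    only — never for training losses.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    peak = float(m0.max())
    if peak <= 0:
        raise MaskError("M0 volume has no positive intensities")
    raw = m0 > fraction * peak
    if not raw.any():
        raise MaskError("threshold produced an empty mask")
    closed = ndimage.binary_closing(raw)
    closed |= raw  # closing with a border can erode; keep original voxels
    labels, n = ndimage.label(closed)
    if n == 0:
        raise MaskError("no connected component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))
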