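"""NIfTI-1 reading and writing for scans.

Each scan is emitted as three files: a 4D difference series (axis order
x, y, z, t), a 3D M0 volume and a 3D brain mask, with an identity affine
scaled by the voxel size.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .synthetic import ASLScan

__all__ = ["write_scan", "load_scan", "load_volume", "save_volume"]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def write_scan(scan: ASLScan, out_dir: str | Path,
               voxel_size=(3.8, 3.8, 3.8)) -> dict[str, Path]:
    """Write series/M0/mask NIfTI files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_size)
    sid = scan.subject_id
    paths = {
        "series": out_dir / f"{sid}_asl.nii",
        "m0": out_dir / f"{sid}_m0.nii",
        "mask": out_dir / f"{sid}_mask.nii",
    }
    series_xyzt = np.moveaxis(scan.series, 0, -1)  # (t,x,y,z) -> (x,y,z,t)
    nib.save(nib.Nifti1Image(series_xyzt.astype(np.float32), aff),
             paths["series"])
    nib.save(nib.Nifti1Image(scan.m0.astype(np.float32), aff), paths["m0"])
    nib.save(nib.Nifti1Image(scan.brain_mask.astype(np.uint8), aff),
             paths["mask"])
    return paths


def load_scan(series_path, m0_path, mask_path=None,
              subject_id: str | None = None, regime: str = "high") -> ASLScan:
    """Assemble an ASLScan from NIfTI files (series stored as x, y, z, t)."""
    series = np.asarray(nib.load(str(series_path)).dataobj, float)
    if series.ndim != 4:
        raise ValueError("series file must be 4D")
    series = np.moveaxis(series, -1, 0)
    m0 = np.asarray(nib.load(str(m0_path)).dataobj, float)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        from .preprocess import brain_mask_from_m0
        mask = brain_mask_from_m0(m0)
    sid = subject_id or Path(series_path).name.split("_")[0]
    return ASLScan(series=series, m0=m0, brain_mask=mask, regime=regime,
                   subject_id=sid)


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, float)


def save_volume(volume: np.ndarray, path,
                voxel_size=(3.8, 3.8, 3.8)) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32),
                             _affine(voxel_size)), str(path))
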