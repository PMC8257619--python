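"""NIfTI-1 I/O helpers (nibabel-backed)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .reconstruct import MPFMap

__all__ = ["save_volume", "load_volume", "save_mpf_map", "load_mpf_map"]


def save_volume(path, data, affine=None, description: str = ""):
    """Write a volume as NIfTI-1; boolean arrays are stored as uint8."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    return Path(path)


def load_volume(path):
    """Read a NIfTI volume; returns ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_mpf_map(mpf_map: MPFMap, out_dir, prefix: str):
    """Write an MPF map with its masks and reconstruction log.

    Produces ``<prefix>_mpf.nii.gz`` (percent units noted in the header),
    ``<prefix>_brain_mask.nii.gz``, ``<prefix>_validity_mask.nii.gz`` and
    ``<prefix>_recon_log.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mpf": save_volume(out_dir / f"{prefix}_mpf.nii.gz",
                           mpf_map.mpf_percent, mpf_map.affine,
                           "MPF map, percent units"),
        "brain_mask": save_volume(out_dir / f"{prefix}_brain_mask.nii.gz",
                                  mpf_map.brain_mask, mpf_map.affine),
        "validity_mask": save_volume(out_dir / f"{prefix}_validity_mask.nii.gz",
                                     mpf_map.validity_mask, mpf_map.affine),
    }
    log_path = out_dir / f"{prefix}_recon_log.json"
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(mpf_map.log, fh, indent=2, default=float)
    paths["log"] = log_path
    return paths


def load_mpf_map(out_dir, prefix: str) -> MPFMap:
    """Read back an MPF map written by :func:`save_mpf_map`."""
    out_dir = Path(out_dir)
    mpf, affine = load_volume(out_dir / f"{prefix}_mpf.nii.gz")
    brain, _ = load_volume(out_dir / f"{prefix}_brain_mask.nii.gz")
    valid, _ = load_volume(out_dir / f"{prefix}_validity_mask.nii.gz")
    log_path = out_dir / f"{prefix}_recon_log.json"
    log = {}
    if log_path.exists():
        with open(log_path, "r", encoding="utf-8") as fh:
            log = json.load(fh)
    return MPFMap(mpf_percent=np.asarray(mpf, dtype=float),
                  brain_mask=np.asarray(brain) > 0,
                  validity_mask=np.asarray(valid) > 0,
                  log=log, affine=affine)
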