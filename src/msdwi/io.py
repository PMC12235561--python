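"""Standard-format export: NIfTI volumes, FSL bvals/bvecs, CSV tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import DiffusionScheme

__all__ = ["export_nifti", "export_bvals_bvecs", "config_hash"]


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a resolved run configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def export_nifti(result, path, voxel_size=(1.0, 1.0, 1.0), what: str = "magnitude"):
    """Write a reconstruction as 4-D NIfTI (x, y, z, q), RAS-like affine.

    ``what`` selects ``magnitude`` or ``phase`` volumes.  The resolved
    configuration hash is stored in the NIfTI description field.
    """
    x = result.x_tilde  # (q, z, ny, nx)
    if what == "magnitude":
        vol = np.abs(x)
    elif what == "phase":
        vol = np.angle(x)
    else:
        raise ValueError(f"unknown export kind {what!r}")
    # (q, z, ny, nx) -> (nx, ny, z, q)
    vol = np.ascontiguousarray(vol.transpose(3, 2, 1, 0))
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    cfg = vars(result.config).copy()
    img.header["descrip"] = f"cfg={config_hash(cfg)}".encode()[:79]
    nib.save(img, str(path))
    return Path(path)


def export_bvals_bvecs(scheme: DiffusionScheme, bvals_path, bvecs_path) -> None:
    """FSL-style text export: one row of b-values, three rows of components."""
    bvals, bvecs = scheme.to_text()
    Path(bvals_path).write_text(bvals)
    Path(bvecs_path).write_text(bvecs)
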