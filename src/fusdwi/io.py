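"""NIfTI-1 / FSL gradient-file I/O and provenance sidecars."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import FormatError
from .gradients import DwiVolume, GradientTable
from .tensor import ScalarMap

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "write_scalar_map",
    "read_gradient_table",
    "write_gradient_table",
    "write_provenance",
]

log = logging.getLogger("fusdwi")


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    """FSL dialect: bvals one whitespace row; bvecs three rows (x, y, z).

    Non-unit nonzero directions are renormalized with a logged warning.
    """
    try:
        bvals = np.loadtxt(bval_path, ndmin=1)
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except OSError as exc:
        raise FormatError(f"cannot read gradient files: {exc}") from exc
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise FormatError(
            f"bvec entries {bvecs.shape} inconsistent with {bvals.size} b-values"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    fix = (bvals > 0) & (np.abs(norms - 1.0) > 1e-9)
    if np.any(fix):
        log.warning("renormalizing %d non-unit gradient direction(s)", int(fix.sum()))
        bvecs = bvecs.copy()
        bvecs[fix] /= norms[fix, None]
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_gradient_table(gradients: GradientTable, bval_path, bvec_path) -> None:
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in gradients.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.10f}" for v in gradients.bvecs[:, axis]) + "\n")


def read_dwi(image_path, bval_path, bvec_path) -> DwiVolume:
    """Load a 4D NIfTI plus its FSL gradient files into a DwiVolume."""
    try:
        img = nib.load(str(image_path))
    except Exception as exc:
        raise FormatError(f"cannot read image {image_path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError("DWI image must be 4D")
    gradients = read_gradient_table(bval_path, bvec_path)
    if data.shape[3] != len(gradients):
        raise FormatError(
            f"{data.shape[3]} image volumes but {len(gradients)} gradient entries"
        )
    voxel_size = float(img.header.get_zooms()[0])
    return DwiVolume(data=data, voxel_size=voxel_size, gradients=gradients)


def write_dwi(dwi: DwiVolume, image_path, bval_path=None, bvec_path=None) -> None:
    img = nib.Nifti1Image(np.asarray(dwi.data, dtype=np.float32), _affine(dwi.voxel_size))
    img.header.set_zooms((dwi.voxel_size,) * 3 + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None and bvec_path is not None:
        write_gradient_table(dwi.gradients, bval_path, bvec_path)


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5


def write_mask(mask: np.ndarray, path, voxel_size: float = 1.0) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size))
    nib.save(img, str(path))


def write_scalar_map(scalar_map: ScalarMap, path) -> None:
    img = nib.Nifti1Image(
        scalar_map.data.astype(np.float32), _affine(scalar_map.voxel_size)
    )
    nib.save(img, str(path))


def write_provenance(path, stage: str, seed: int, config: dict) -> None:
    """JSON sidecar recording the stage, seed and the exact configuration."""
    from . import __version__

    payload = {
        "stage": stage,
        "seed": int(seed),
        "fusdwi_version": __version__,
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
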