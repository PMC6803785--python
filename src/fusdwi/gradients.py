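"""Gradient tables, the monoexponential tensor signal model, and the DWI container.

Conventions
-----------
* b-values are in s/mm^2, diffusivities in mm^2/s, so b*lambda is dimensionless.
* Gradient directions are unit 3-vectors; the zero vector is only allowed on
  b=0 entries.
* Voxel centers sit at integer index times ``voxel_size`` (identity world
  transform, 0-based indexing, mm units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GradientTable", "DwiVolume", "make_gradient_table", "tensor_signal"]

_UNIT_NORM_TOL = 1e-9


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (n,) array
        Diffusion weighting per volume, s/mm^2.
    bvecs : (n, 3) array
        Unit direction per volume; rows with b=0 may be the zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be nonnegative")
        if not np.any(bvals == 0):
            raise ValueError("gradient table must contain at least one b=0 entry")
        norms = np.linalg.norm(bvecs, axis=1)
        nonzero = bvals > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > _UNIT_NORM_TOL):
            raise ValueError("nonzero-b directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def shells(self) -> np.ndarray:
        """Distinct nonzero b-values."""
        return np.unique(self.bvals[self.bvals > 0])


@dataclass
class DwiVolume:
    """A 4D diffusion-weighted acquisition on a regular isotropic grid.

    ``data`` is indexed (x, y, z, volume); the 4th axis matches the gradient
    table entry-for-entry.
    """

    data: np.ndarray
    voxel_size: float
    gradients: GradientTable

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, volume)")
        if data.shape[3] != len(self.gradients):
            raise ValueError(
                f"{data.shape[3]} volumes but {len(self.gradients)} gradient entries"
            )
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if np.any(data < 0):
            raise ValueError("DWI intensities must be nonnegative")
        self.data = data

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def make_gradient_table(n_directions: int, b: float) -> GradientTable:
    """Build a single-shell table: one b=0 entry plus ``n_directions`` at ``b``.

    Directions are a deterministic spherical-Fibonacci lattice, which is
    quasi-uniform on the sphere and reproducible across runs (the vendor
    schemes used on clinical scanners are not published).

    Parameters
    ----------
    n_directions : int
        Number of diffusion-weighted directions; at least 6, otherwise the
        six-parameter tensor is underdetermined.
    b : float
        Shell b-value in s/mm^2, positive.
    """
    if n_directions < 6:
        raise ValueError("need at least 6 directions to determine a tensor")
    if b <= 0:
        raise ValueError("b must be positive")
    i = np.arange(n_directions)
    # Spherical Fibonacci lattice: uniform-area bands in z, golden-angle azimuth.
    z = 1.0 - (2.0 * i + 1.0) / n_directions
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def tensor_signal(s0: float, D: np.ndarray, gradients: GradientTable) -> np.ndarray:
    """Noise-free Stejskal-Tanner signal S_i = s0 * exp(-b_i g_i^T D g_i).

    ``D`` must be a symmetric 3x3 diffusion tensor (mm^2/s).  The b=0 entries
    return exactly ``s0``.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValueError("D must be a 3x3 matrix")
    if not np.allclose(D, D.T, atol=1e-12, rtol=0.0):
        raise ValueError("D must be symmetric")
    quad = np.einsum("gi,ij,gj->g", gradients.bvecs, D, gradients.bvecs)
    return s0 * np.exp(-gradients.bvals * quad)
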