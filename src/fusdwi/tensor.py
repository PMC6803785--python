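"""Per-voxel diffusion tensor fitting and scalar metric maps.

``DiffusionTensorModel`` fits, at each masked voxel, the log-linear
least-squares system

    ln S_i = ln s0 - b_i g_i^T D g_i

for the six unique tensor elements and ln s0.  ``TensorFitResults`` carries
the eigen-decomposition (eigenvalues sorted descending, clamped at 0) and
derives the scalar maps:

* AD = lambda1, RD = (lambda2 + lambda3)/2, MD = mean(lambda)
* FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||  (0 for the zero tensor)

MDWI (mean of all volumes, b=0 included) and ADC (monoexponential estimate
from the mean diffusion-weighted signal) come straight from the signals and
do not need a tensor fit.  ADC is kept distinct from MD on purpose: averaging
signals before taking the log weights the directional decays differently from
averaging the exponents, so for anisotropic voxels ADC <= MD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, UnsupportedShellStructureError
from .gradients import DwiVolume, GradientTable

__all__ = [
    "ScalarMap",
    "TensorFitResults",
    "DiffusionTensorModel",
    "fit_tensor_loglinear",
    "eigen_metrics",
    "compute_mdwi",
    "compute_adc",
]

METRIC_KINDS = ("FA", "MD", "AD", "RD", "ADC", "MDWI")


@dataclass
class ScalarMap:
    """A per-voxel scalar image with its metric kind and units.

    Invalid voxels are NaN; ``valid_mask`` exposes them explicitly.
    """

    data: np.ndarray
    metric_kind: str
    units: str
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.metric_kind not in METRIC_KINDS:
            raise ValueError(f"metric_kind must be one of {METRIC_KINDS}")
        self.data = np.asarray(self.data, dtype=float)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)


def _design_matrix(gradients: GradientTable) -> np.ndarray:
    b = gradients.bvals[:, None]
    g = gradients.bvecs
    return np.hstack(
        [
            np.ones((len(gradients), 1)),
            -b * g[:, [0]] ** 2,
            -b * g[:, [1]] ** 2,
            -b * g[:, [2]] ** 2,
            -2 * b * g[:, [0]] * g[:, [1]],
            -2 * b * g[:, [0]] * g[:, [2]],
            -2 * b * g[:, [1]] * g[:, [2]],
        ]
    )


class DiffusionTensorModel:
    """Ordinary log-linear single-tensor model for one DWI acquisition.

    Parameters
    ----------
    dwi : DwiVolume
        Needs at least one b=0 volume and six diffusion-weighted volumes.
    mask : bool array, optional
        Voxels to fit; defaults to everything.
    """

    def __init__(self, dwi: DwiVolume, mask: np.ndarray | None = None):
        g = dwi.gradients
        if int(g.dwi_mask.sum()) < 6 or int(g.b0_mask.sum()) < 1:
            raise InsufficientDataError(
                "need >= 6 b>0 volumes and >= 1 b=0 volume for a tensor fit"
            )
        if mask is None:
            mask = np.ones(dwi.grid_shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dwi.grid_shape:
            raise ValueError("mask shape does not match the DWI grid")
        self.dwi = dwi
        self.mask = mask
        self.design = _design_matrix(g)

    def fit(self) -> "TensorFitResults":
        dwi, mask = self.dwi, self.mask
        signals = dwi.data[mask].astype(float)  # (n, m)
        positive = np.all(signals > 0, axis=1)
        fitted = np.zeros_like(positive)
        coeffs = np.zeros((signals.shape[0], 7))
        if np.any(positive):
            pinv = np.linalg.pinv(self.design)
            coeffs[positive] = np.log(signals[positive]) @ pinv.T
            fitted = positive

        shape = dwi.grid_shape
        tensors = np.full(shape + (3, 3), np.nan)
        s0_map = np.full(shape, np.nan)
        valid = np.zeros(shape, dtype=bool)

        dxx, dyy, dzz, dxy, dxz, dyz = (coeffs[:, k] for k in range(1, 7))
        tens = np.empty((signals.shape[0], 3, 3))
        tens[:, 0, 0], tens[:, 1, 1], tens[:, 2, 2] = dxx, dyy, dzz
        tens[:, 0, 1] = tens[:, 1, 0] = dxy
        tens[:, 0, 2] = tens[:, 2, 0] = dxz
        tens[:, 1, 2] = tens[:, 2, 1] = dyz

        evals = np.full(shape + (3,), np.nan)
        evecs = np.full(shape + (3, 3), np.nan)
        n_clamped = 0
        if np.any(fitted):
            w, v = np.linalg.eigh(tens[fitted])  # ascending
            w = w[:, ::-1]
            v = v[:, :, ::-1]
            n_clamped = int(np.sum(np.any(w < 0, axis=1)))
            w = np.clip(w, 0.0, None)

            idx = np.zeros(mask.sum(), dtype=bool)
            idx[fitted] = True
            full_idx = np.zeros(shape, dtype=bool)
            full_idx[mask] = idx
            tensors[full_idx] = tens[fitted]
            s0_full = np.full(mask.sum(), np.nan)
            s0_full[fitted] = np.exp(coeffs[fitted, 0])
            s0_map[mask] = s0_full
            ev_full = np.full((mask.sum(), 3), np.nan)
            ev_full[fitted] = w
            evals[mask] = ev_full
            vec_full = np.full((mask.sum(), 3, 3), np.nan)
            vec_full[fitted] = v
            evecs[mask] = vec_full
            valid = full_idx

        return TensorFitResults(
            tensors=tensors,
            s0_map=s0_map,
            eigenvalues=evals,
            eigenvectors=evecs,
            valid_mask=valid,
            n_clamped=n_clamped,
            voxel_size=dwi.voxel_size,
        )


@dataclass
class TensorFitResults:
    """Per-voxel tensors, eigen-decomposition and derived scalar maps.

    ``eigenvectors[..., :, k]`` is the unit eigenvector of
    ``eigenvalues[..., k]``; eigenvalues are sorted descending and clamped at
    zero (``n_clamped`` voxels needed clamping).
    """

    tensors: np.ndarray
    s0_map: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    valid_mask: np.ndarray
    n_clamped: int
    voxel_size: float = 1.0

    def _map(self, data: np.ndarray, kind: str, units: str) -> ScalarMap:
        out = np.full(self.valid_mask.shape, np.nan)
        out[self.valid_mask] = data[self.valid_mask]
        return ScalarMap(out, kind, units, self.voxel_size)

    def ad(self) -> ScalarMap:
        return self._map(self.eigenvalues[..., 0], "AD", "mm^2/s")

    def rd(self) -> ScalarMap:
        return self._map(self.eigenvalues[..., 1:].mean(axis=-1), "RD", "mm^2/s")

    def md(self) -> ScalarMap:
        return self._map(self.eigenvalues.mean(axis=-1), "MD", "mm^2/s")

    def fa(self) -> ScalarMap:
        lam = self.eigenvalues
        mean = lam.mean(axis=-1, keepdims=True)
        num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
        den = np.sqrt(np.sum(lam**2, axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
        return self._map(np.clip(fa, 0.0, 1.0), "FA", "dimensionless")

    def scalar_maps(self) -> dict:
        return {"FA": self.fa(), "MD": self.md(), "AD": self.ad(), "RD": self.rd()}

    def summary(self) -> str:
        n = int(self.valid_mask.sum())
        lines = [
            "Diffusion tensor fit (log-linear least squares)",
            f"  fitted voxels : {n}",
            f"  clamped voxels: {self.n_clamped}",
        ]
        if n:
            for kind, m in self.scalar_maps().items():
                vals = m.data[self.valid_mask]
                lines.append(f"  {kind:<4} mean {np.nanmean(vals):.6g}  "
                             f"range [{np.nanmin(vals):.6g}, {np.nanmax(vals):.6g}]")
        return "\n".join(lines)


def fit_tensor_loglinear(dwi: DwiVolume, mask: np.ndarray | None = None) -> TensorFitResults:
    """Functional wrapper: ``DiffusionTensorModel(dwi, mask).fit()``."""
    return DiffusionTensorModel(dwi, mask).fit()


def eigen_metrics(results: TensorFitResults) -> dict:
    """The four tensor-derived scalar maps {FA, MD, AD, RD}."""
    return results.scalar_maps()


def compute_mdwi(dwi: DwiVolume) -> ScalarMap:
    """Mean diffusion-weighted image: voxel-wise mean of ALL volumes, b=0 included."""
    return ScalarMap(
        dwi.data.mean(axis=3, dtype=float), "MDWI", "intensity", dwi.voxel_size
    )


def compute_adc(dwi: DwiVolume) -> ScalarMap:
    """Monoexponential ADC from the mean DW signal over the single shell.

    ADC = -(1/b) ln(mean_dw / mean_b0); voxels where the ratio is nonpositive
    are invalid (NaN).
    """
    g = dwi.gradients
    shells = g.shells
    if shells.size != 1:
        raise UnsupportedShellStructureError(
            f"ADC needs exactly one nonzero b-value, found {shells.size}"
        )
    b = float(shells[0])
    s_dw = dwi.data[..., g.dwi_mask].mean(axis=3, dtype=float)
    s_0 = dwi.data[..., g.b0_mask].mean(axis=3, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s_dw / s_0
        adc = np.where(ratio > 0, -np.log(np.where(ratio > 0, ratio, 1.0)) / b, np.nan)
    return ScalarMap(adc, "ADC", "mm^2/s", dwi.voxel_size)
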