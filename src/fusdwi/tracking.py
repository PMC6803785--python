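"""Deterministic single-tensor streamline tracking and the tract-disruption assay.

From each seed the tracker integrates bidirectionally along the principal
eigenvector of the trilinearly interpolated tensor (component-wise
interpolation of the six unique elements, then eigen-decomposition, sign
aligned with the previous step).  A step is taken only if the new point is
inside the grid and its interpolated FA is at or above the termination
cutoff, so streamlines stop AT a low-FA face and never enter it.  Curvature
is enforced as a per-step maximum turning angle of
``2 asin(step / (2 R_min))`` — the exact discrete analogue of a circular arc
of radius ``R_min``.  Streamlines shorter than the minimum length are
discarded.

The FA cutoff of 0.15 mirrors the conventional tracking amplitude threshold;
for a single-tensor tracker FA is the natural termination scalar and the
value is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrackingParams",
    "Streamline",
    "seed_points",
    "track",
    "disruption_assay",
    "streamline_length",
    "save_streamlines_text",
    "save_trk",
]


@dataclass(frozen=True)
class TrackingParams:
    """Step size, curvature bound, FA cutoff and length window (mm)."""

    step: float = 0.1
    min_curvature_radius: float = 1.0
    termination_cutoff: float = 0.15
    min_length: float = 5.0
    max_length: float = 250.0

    def __post_init__(self) -> None:
        if min(self.step, self.min_curvature_radius, self.termination_cutoff,
               self.min_length, self.max_length) <= 0:
            raise ValueError("all tracking parameters must be positive")
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be below max_length")

    @property
    def max_turn_angle(self) -> float:
        """Largest allowed angle (radians) between consecutive steps."""
        return 2.0 * np.arcsin(min(1.0, self.step / (2.0 * self.min_curvature_radius)))


@dataclass
class Streamline:
    """An ordered polyline in mm with the index of the seed that spawned it."""

    points: np.ndarray  # (n, 3)
    seed_index: int

    def __len__(self) -> int:
        return self.points.shape[0]


def streamline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def seed_points(mask: np.ndarray, per_voxel: int, seed: int,
                voxel_size: float = 1.0, jitter: bool = True) -> np.ndarray:
    """Seed positions (mm): ``per_voxel`` jittered points per mask voxel.

    With ``jitter=False`` every seed sits at the voxel center.  Deterministic
    for a given ``seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if per_voxel < 1:
        raise ValueError("per_voxel must be >= 1")
    centers = np.argwhere(mask).astype(float)
    if centers.size == 0:
        raise ValueError("seed mask is empty")
    centers = np.repeat(centers, per_voxel, axis=0)
    if jitter:
        rng = np.random.default_rng(seed)
        centers = centers + rng.uniform(-0.5, 0.5, size=centers.shape)
    return centers * voxel_size


class _TrilinearField:
    """Trilinear interpolation of a multi-channel voxel-center field."""

    def __init__(self, data: np.ndarray):
        # data: (X, Y, Z, C); NaN channels treated as 0 (invalid voxels
        # contribute nothing, which also drags interpolated FA down there)
        self.data = np.nan_to_num(np.asarray(data, dtype=float), nan=0.0)
        self.dims = np.asarray(data.shape[:3])

    def inside(self, p_vox: np.ndarray) -> bool:
        return bool(np.all(p_vox >= 0.0) and np.all(p_vox <= self.dims - 1))

    def __call__(self, p_vox: np.ndarray) -> np.ndarray:
        i0 = np.floor(p_vox).astype(int)
        i0 = np.minimum(i0, self.dims - 2)
        i0 = np.maximum(i0, 0)
        f = p_vox - i0
        d = self.data
        x0, y0, z0 = i0
        c = d[x0:x0 + 2, y0:y0 + 2, z0:z0 + 2]  # (2,2,2,C)
        wx = np.array([1 - f[0], f[0]])
        wy = np.array([1 - f[1], f[1]])
        wz = np.array([1 - f[2], f[2]])
        return np.einsum("i,j,k,ijkc->c", wx, wy, wz, c)


def _principal_direction(six: np.ndarray) -> np.ndarray:
    D = np.array(
        [
            [six[0], six[3], six[4]],
            [six[3], six[1], six[5]],
            [six[4], six[5], six[2]],
        ]
    )
    w, v = np.linalg.eigh(D)
    return v[:, 2]


def _half_track(p0_vox, v0, tensor_field, fa_field, params, voxel_size, budget):
    """March from p0 along v0; returns points AFTER p0 (voxel coords)."""
    step_vox = params.step / voxel_size
    cos_max = np.cos(params.max_turn_angle)
    pts = []
    p, v = p0_vox.copy(), v0.copy()
    for _ in range(budget):
        p_next = p + step_vox * v
        if not tensor_field.inside(p_next):
            break
        if fa_field(p_next)[0] < params.termination_cutoff:
            break
        pts.append(p_next.copy())
        v_new = _principal_direction(tensor_field(p_next))
        if np.dot(v_new, v) < 0:
            v_new = -v_new
        if np.dot(v_new, v) < cos_max:
            break
        p, v = p_next, v_new
    return pts


def track(seeds: np.ndarray, field, fa, params: TrackingParams | None = None) -> list:
    """Bidirectional deterministic tracking from each seed.

    Parameters
    ----------
    seeds : (n, 3) array
        Seed positions in mm (e.g. from :func:`seed_points`).
    field : TensorFitResults
        Fitted tensor field; its ``tensors`` are interpolated component-wise.
    fa : ScalarMap
        FA map aligned with the field, used for termination.
    params : TrackingParams

    Returns
    -------
    list of Streamline whose total length is within the length window.
    Seeds in sub-cutoff or invalid voxels produce nothing.
    """
    if params is None:
        params = TrackingParams()
    voxel_size = fa.voxel_size
    t = field.tensors
    six = np.stack(
        [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2],
         t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]],
        axis=-1,
    )
    tensor_field = _TrilinearField(six)
    fa_field = _TrilinearField(fa.data[..., None])
    # the length cap applies to the whole streamline; split it between halves
    budget = int(np.floor(params.max_length / (2.0 * params.step)))

    out = []
    for idx, seed_mm in enumerate(np.atleast_2d(np.asarray(seeds, dtype=float))):
        p0 = seed_mm / voxel_size
        if not tensor_field.inside(p0):
            continue
        if fa_field(p0)[0] < params.termination_cutoff:
            continue
        v0 = _principal_direction(tensor_field(p0))
        fwd = _half_track(p0, v0, tensor_field, fa_field, params, voxel_size, budget)
        bwd = _half_track(p0, -v0, tensor_field, fa_field, params, voxel_size, budget)
        pts = bwd[::-1] + [p0] + fwd
        points_mm = np.asarray(pts) * voxel_size
        length = (len(pts) - 1) * params.step
        if length >= params.min_length:
            out.append(Streamline(points=points_mm, seed_index=idx))
    return out


def _points_in_mask(points_mm: np.ndarray, mask: np.ndarray, voxel_size: float) -> bool:
    idx = np.rint(points_mm / voxel_size).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    if not np.any(ok):
        return False
    idx = idx[ok]
    return bool(np.any(mask[idx[:, 0], idx[:, 1], idx[:, 2]]))


def disruption_assay(streamlines_pre: list, streamlines_post: list,
                     lesion_core: np.ndarray, distal_seed: np.ndarray,
                     far_target: np.ndarray, voxel_size: float = 1.0):
    """Count distal-seeded streamlines that reach the far target or enter the core.

    For each timepoint, among streamlines passing through ``distal_seed``
    (which includes every streamline whose seed was placed there), reports how
    many have any point inside ``far_target`` (tract continuity) and how many
    have any point inside ``lesion_core``.  After ablation the core FA falls
    below the tracking cutoff, so post-treatment streamlines stop at the
    lesion face and the reach count collapses.
    """
    rows = []
    for timepoint, streams in (("pre", streamlines_pre), ("post", streamlines_post)):
        seeded = [
            s for s in streams if _points_in_mask(s.points, distal_seed, voxel_size)
        ]
        rows.append(
            {
                "timepoint": timepoint,
                "n_seeded": len(seeded),
                "n_reach_target": sum(
                    _points_in_mask(s.points, far_target, voxel_size) for s in seeded
                ),
                "n_enter_lesion": sum(
                    _points_in_mask(s.points, lesion_core, voxel_size) for s in seeded
                ),
            }
        )
    return pd.DataFrame(rows)


def save_streamlines_text(path, streamlines: list) -> None:
    """Plain-text streamlines: one 'x y z' point per line, blank line between."""
    with open(path, "w") as fh:
        for k, s in enumerate(streamlines):
            if k:
                fh.write("\n")
            for p in s.points:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def save_trk(path, streamlines: list, grid_shape, voxel_size: float = 1.0) -> None:
    """TrackVis TRK output with an identity voxel-to-world affine."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram
    from nibabel.streamlines.trk import TrkFile

    affine = np.diag([voxel_size] * 3 + [1.0])
    tractogram = Tractogram([s.points for s in streamlines], affine_to_rasmm=np.eye(4))
    header = {
        "dimensions": np.asarray(grid_shape, dtype=np.int16),
        "voxel_sizes": np.asarray([voxel_size] * 3, dtype=np.float32),
        "voxel_to_rasmm": affine.astype(np.float32),
        "voxel_order": "RAS",
    }
    TrkFile(tractogram, header).save(str(path))
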