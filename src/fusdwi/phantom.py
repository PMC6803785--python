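"""Seeded DWI phantoms of a small-animal brain with a focal thermal lesion.

The phantom emulates the acquisition used for acute focused-ultrasound lesion
assessment: ~1 mm isotropic voxels, one b=0 volume plus 128 directions at
b=800 s/mm^2, an anisotropic C-shaped white-matter tract (fornix analogue), a
splenium-like anisotropic reference region, and an ellipsoidal lesion whose
diffusivity suppression peaks at the core and decays radially.  Suppressed
diffusivity raises the diffusion-weighted signal, so the lesion appears
hyperintense on the mean DWI (MDWI) without being painted in explicitly.

Lesion effect model
-------------------
At normalized ellipsoidal radius r the scale factor is
``s = core_scale + (1 - core_scale) * min(r, 1)``.  The post-treatment
eigenvalues at that voxel are

    lambda_i' = s * mean(lambda) * (lambda_i / mean(lambda)) ** (s ** 2)

i.e. the tensor magnitude is multiplied by s while eigenvalue ratios are
shrunk toward 1 with exponent s^2.  Coagulative necrosis both restricts
diffusion and destroys the oriented axonal substrate, so FA falls together
with the diffusivities; a pure magnitude scaling would leave FA untouched.
At s=1 the tensor is exactly unchanged, so the effect vanishes continuously
at the lesion rim.  Eigenvectors are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidGeometryError
from .gradients import DwiVolume, GradientTable, make_gradient_table

__all__ = [
    "PhantomSpec",
    "Phantom",
    "lesion_scale_profile",
    "make_phantom",
    "small_phantom_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one simulated pre/post acquisition pair.

    Distances are mm; the grid is isotropic with voxel centers at integer
    index * ``voxel_size``.  Eigenvalue triples are (lambda1, lambda2,
    lambda3) in mm^2/s, sorted descending.
    """

    grid_shape: tuple = (64, 80, 56)
    voxel_size: float = 1.0
    background_evals: tuple = (0.9e-3, 0.8e-3, 0.7e-3)
    tract_evals: tuple = (1.7e-3, 0.3e-3, 0.3e-3)
    reference_evals: tuple = (1.7e-3, 0.3e-3, 0.3e-3)
    brain_semi_axes: tuple = (26.0, 33.0, 22.0)
    tract_arc_radius: float = 20.0
    tract_tube_radius: float = 1.0
    tract_arc_span_deg: tuple = (30.0, 150.0)
    reference_center_offset: tuple = (0.0, 22.0, -4.0)
    reference_radius: float = 2.5
    lesion_center: tuple | None = None  # default: tract apex (grid center)
    lesion_semi_axes: tuple = (4.0, 4.0, 6.0)
    lesion_core_scale: float = 0.25
    n_directions: int = 128
    b_value: float = 800.0
    s0: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_evals", "tract_evals", "reference_evals"):
            ev = np.asarray(getattr(self, name), dtype=float)
            if ev.shape != (3,) or np.any(ev < 0) or np.any(np.diff(ev) > 0):
                raise ValueError(f"{name} must be 3 nonnegative values sorted descending")
        if not 0.0 < self.lesion_core_scale <= 1.0:
            raise ValueError("lesion_core_scale must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.voxel_size <= 0 or self.s0 <= 0:
            raise ValueError("voxel_size and s0 must be positive")

    @property
    def grid_center(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size

    @property
    def lesion_center_mm(self) -> np.ndarray:
        if self.lesion_center is not None:
            return np.asarray(self.lesion_center, dtype=float)
        # tract apex: top of the arc, at the grid center by construction
        return self.grid_center


@dataclass
class Phantom:
    """Output bundle of :func:`make_phantom`."""

    pre: DwiVolume
    post: DwiVolume
    masks: dict  # brain, lesion, tract, reference, distal_seed, far_target
    spec: PhantomSpec


def lesion_scale_profile(r, core_scale: float):
    """Radial diffusivity scale: ``core_scale`` at the core, 1 at/beyond the rim.

    Linear in the normalized ellipsoidal radius ``r`` (monotone non-decreasing),
    matching the observed pattern of peak change at the lesion core decreasing
    radially outward.
    """
    if core_scale <= 0 or core_scale > 1:
        raise ValueError("core_scale must lie in (0, 1]")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be nonnegative")
    out = core_scale + (1.0 - core_scale) * np.minimum(r, 1.0)
    return out if out.ndim else float(out)


def _voxel_coords_mm(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    x = np.arange(nx) * spec.voxel_size
    y = np.arange(ny) * spec.voxel_size
    z = np.arange(nz) * spec.voxel_size
    return np.meshgrid(x, y, z, indexing="ij", sparse=False)


def _build_geometry(spec: PhantomSpec):
    """Masks, per-voxel eigen-frames and eigenvalues for the pre phantom."""
    X, Y, Z = _voxel_coords_mm(spec)
    cx, cy, cz = spec.grid_center
    ax, ay, az = spec.brain_semi_axes
    brain = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0

    # C-shaped tract: circular arc of radius R in the mid-sagittal (y, z)
    # plane, arc center below the grid center so the apex sits at the center.
    R = spec.tract_arc_radius
    arc_cy, arc_cz = cy, cz - R
    dy, dz = Y - arc_cy, Z - arc_cz
    rho = np.hypot(dy, dz)
    theta = np.degrees(np.arctan2(dz, dy))  # 90 deg at the apex
    lo, hi = spec.tract_arc_span_deg
    in_span = (theta >= lo) & (theta <= hi)
    dist_to_arc = np.sqrt((X - cx) ** 2 + (rho - R) ** 2)
    tract = in_span & (dist_to_arc <= spec.tract_tube_radius)

    ref_center = spec.grid_center + np.asarray(spec.reference_center_offset)
    ref = (
        (X - ref_center[0]) ** 2 + (Y - ref_center[1]) ** 2 + (Z - ref_center[2]) ** 2
        <= spec.reference_radius**2
    )

    lc = spec.lesion_center_mm
    la = np.asarray(spec.lesion_semi_axes, dtype=float)
    r_lesion = np.sqrt(
        ((X - lc[0]) / la[0]) ** 2 + ((Y - lc[1]) / la[1]) ** 2 + ((Z - lc[2]) / la[2]) ** 2
    )
    lesion = r_lesion < 1.0

    for name, m in (("lesion", lesion), ("tract", tract), ("reference", ref)):
        if np.any(m & ~brain):
            raise InvalidGeometryError(f"{name} region extends outside the brain mask")
    if not np.any(lesion):
        raise InvalidGeometryError("lesion ellipsoid contains no voxel centers")

    # Seed/target segments at the two ends of the arc, for the disruption assay.
    seed_span = (lo, lo + 15.0)
    target_span = (hi - 15.0, hi)
    distal_seed = tract & (theta >= seed_span[0]) & (theta <= seed_span[1])
    far_target = tract & (theta >= target_span[0]) & (theta <= target_span[1])

    # Per-voxel eigenvalues and orthonormal frames (columns = eigenvectors).
    shape = spec.grid_shape
    evals = np.zeros(shape + (3,))
    frames = np.zeros(shape + (3, 3))
    evals[brain] = np.asarray(spec.background_evals)
    frames[brain] = np.eye(3)  # lambda1 along x, lambda2 along y, lambda3 along z

    # Tract: principal axis tangent to the arc, (0, -sin t, cos t); the two
    # minor axes complete the triad with x-hat.
    th = np.radians(theta[tract])
    e1 = np.column_stack([np.zeros_like(th), -np.sin(th), np.cos(th)])
    e2 = np.tile([1.0, 0.0, 0.0], (th.size, 1))
    e3 = np.cross(e1, e2)
    fr = np.stack([e1, e2, e3], axis=-1)
    frames[tract] = fr
    evals[tract] = np.asarray(spec.tract_evals)

    # Reference: splenium-like, fibers crossing left-right (principal axis x).
    frames[ref] = np.eye(3)
    evals[ref] = np.asarray(spec.reference_evals)

    masks = {
        "brain": brain,
        "lesion": lesion,
        "tract": tract,
        "reference": ref,
        "distal_seed": distal_seed,
        "far_target": far_target,
    }
    return masks, evals, frames, r_lesion


def _apply_lesion(evals: np.ndarray, lesion: np.ndarray, r_lesion: np.ndarray,
                  core_scale: float) -> np.ndarray:
    """Post-treatment eigenvalues: magnitude scale + anisotropy shrinkage."""
    out = evals.copy()
    lam = evals[lesion]
    s = np.asarray(lesion_scale_profile(r_lesion[lesion], core_scale))[:, None]
    mean = lam.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > 0, lam / mean, 1.0)
        shrunk = s * mean * ratio ** (s**2)
    # shrinkage can reorder eigenvalues for strongly anisotropic input;
    # re-sort so the descending convention holds
    out[lesion] = -np.sort(-shrunk, axis=1)
    return out


def _signals(evals, frames, mask, gradients: GradientTable, s0: float) -> np.ndarray:
    """Noise-free signals for masked voxels, shape (n_masked, n_volumes)."""
    lam = evals[mask]  # (n, 3)
    fr = frames[mask]  # (n, 3, 3), columns are eigenvectors
    g = gradients.bvecs  # (m, 3)
    # g^T D g = sum_k lambda_k (g . e_k)^2
    proj = np.einsum("gi,nik->ngk", g, fr)  # (n, m, 3)
    quad = np.einsum("ngk,nk->ng", proj**2, lam)
    return s0 * np.exp(-gradients.bvals[None, :] * quad)


def _assemble(clean: np.ndarray, mask: np.ndarray, shape: tuple, n_vol: int,
              sigma: float, rng: np.random.Generator) -> np.ndarray:
    data = np.zeros(shape + (n_vol,), dtype=np.float32)
    if sigma > 0:
        # Rician magnitude: |clean + noise_re + i*noise_im|
        n1 = rng.normal(0.0, sigma, clean.shape)
        n2 = rng.normal(0.0, sigma, clean.shape)
        data[mask] = np.sqrt((clean + n1) ** 2 + n2**2).astype(np.float32)
    else:
        data[mask] = clean.astype(np.float32)
    return data


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Simulate the pre/post acquisition pair plus ground-truth masks.

    Pre and post volumes are identical except inside the lesion ellipsoid,
    where the post-treatment tensors are suppressed by the radial profile;
    Rician noise (two independent Gaussian channels) is drawn independently
    for the two timepoints from the spec seed, so identical specs give
    bit-identical outputs.
    """
    masks, evals_pre, frames, r_lesion = _build_geometry(spec)
    gradients = make_gradient_table(spec.n_directions, spec.b_value)
    brain = masks["brain"]

    evals_post = _apply_lesion(evals_pre, masks["lesion"], r_lesion, spec.lesion_core_scale)

    clean_pre = _signals(evals_pre, frames, brain, gradients, spec.s0)
    clean_post = _signals(evals_post, frames, brain, gradients, spec.s0)

    ss = np.random.SeedSequence(spec.seed)
    rng_pre, rng_post = (np.random.default_rng(c) for c in ss.spawn(2))
    shape, n_vol = spec.grid_shape, len(gradients)
    pre = DwiVolume(
        _assemble(clean_pre, brain, shape, n_vol, spec.noise_sigma, rng_pre),
        spec.voxel_size, gradients,
    )
    post = DwiVolume(
        _assemble(clean_post, brain, shape, n_vol, spec.noise_sigma, rng_post),
        spec.voxel_size, gradients,
    )
    return Phantom(pre=pre, post=post, masks=masks, spec=spec)


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A reduced-grid spec for replicate studies and fast tests.

    Same tissue classes, acquisition scheme and layout as the default, on a
    28 x 36 x 26 grid; geometry is scaled so the lesion still straddles the
    tract apex and all regions stay inside the brain.
    """
    base = dict(
        grid_shape=(28, 36, 26),
        brain_semi_axes=(12.0, 16.0, 11.0),
        tract_arc_radius=9.0,
        reference_center_offset=(0.0, 10.0, 3.0),
        reference_radius=2.0,
        lesion_semi_axes=(3.0, 3.0, 4.0),
    )
    base.update(overrides)
    return PhantomSpec(**base)
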