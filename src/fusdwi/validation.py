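"""Self-validation studies run by the test suite and the acceptance script.

Each function builds its own inputs from the synthetic generator (or from
random tensors), runs the package end to end, and returns plain numbers, so
the same code backs the automated checks and reproducibility reports.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .gradients import DwiVolume, make_gradient_table, tensor_signal
from .phantom import PhantomSpec, make_phantom, small_phantom_spec
from .segmentation import extract_lesion, make_layers, select_cutoff
from .stats import build_layer_report
from .tensor import DiffusionTensorModel, compute_adc, compute_mdwi
from .tracking import TrackingParams, disruption_assay, seed_points, streamline_length, track

__all__ = [
    "random_spd_tensors",
    "tensor_recovery_error",
    "fit_maps",
    "segmentation_recovery",
    "layered_effect",
    "null_calibration",
    "audit_streamlines",
    "disruption_study",
]


def random_spd_tensors(n: int, seed: int, scale: float = 1e-3) -> np.ndarray:
    """Random symmetric positive-definite 3x3 tensors with realistic magnitude."""
    rng = np.random.default_rng(seed)
    out = np.empty((n, 3, 3))
    for k in range(n):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        lam = rng.uniform(0.1, 2.5, size=3) * scale
        out[k] = q @ np.diag(lam) @ q.T
    return out


def tensor_recovery_error(n: int = 100, seed: int = 0) -> float:
    """Max relative eigenvalue error of the log-linear fit on noiseless signals.

    The forward signals come from the closed-form monoexponential model; the
    fit solves a consistent linear system, so the error is numerical only.
    """
    gt = make_gradient_table(32, 800.0)
    tensors = random_spd_tensors(n, seed)
    signals = np.stack([tensor_signal(1000.0, D, gt) for D in tensors])
    dwi = DwiVolume(signals.reshape(n, 1, 1, len(gt)), 1.0, gt)
    results = DiffusionTensorModel(dwi).fit()
    fitted = results.eigenvalues.reshape(n, 3)
    truth = np.sort(np.linalg.eigvalsh(tensors), axis=1)[:, ::-1]
    return float(np.max(np.abs(fitted - truth) / truth))


def fit_maps(dwi: DwiVolume, mask: np.ndarray) -> dict:
    """All six scalar maps for one acquisition (tensor fit + ADC + MDWI)."""
    fit = DiffusionTensorModel(dwi, mask).fit()
    maps = fit.scalar_maps()
    maps["ADC"] = compute_adc(dwi)
    maps["MDWI"] = compute_mdwi(dwi)
    return maps


def _surface_voxels(mask: np.ndarray) -> int:
    struct = ndimage.generate_binary_structure(3, 1)
    return int((mask & ~ndimage.binary_erosion(mask, struct)).sum())


def segmentation_recovery(seed: int = 0, noise_sigma: float = 20.0) -> dict:
    """Segmentation accuracy against generator truth on the default phantom.

    Returns the noiseless volume error (with the analytic ellipsoid volume
    and its surface-voxel tolerance) and the Dice coefficient at the given
    noise level (default sigma = s0/50, i.e. SNR 50).
    """
    out = {}
    truth_volume = None
    for label, sigma in (("noiseless", 0.0), ("noisy", noise_sigma)):
        ph = make_phantom(PhantomSpec(seed=seed, noise_sigma=sigma))
        brain, lesion = ph.masks["brain"], ph.masks["lesion"]
        mdwi = compute_mdwi(ph.post)
        region = extract_lesion(mdwi, select_cutoff(mdwi, brain), brain)
        inter = int((region & lesion).sum())
        dice = 2.0 * inter / (int(region.sum()) + int(lesion.sum()))
        if label == "noiseless":
            semi = np.asarray(ph.spec.lesion_semi_axes)
            truth_volume = 4.0 / 3.0 * np.pi * np.prod(semi)
            out["volume_error_mm3"] = abs(
                float(region.sum()) * ph.spec.voxel_size**3 - truth_volume
            )
            out["surface_tolerance_mm3"] = _surface_voxels(lesion) * ph.spec.voxel_size**3
            out["analytic_volume_mm3"] = float(truth_volume)
            out["dice_noiseless"] = dice
        else:
            out["dice_snr50"] = dice
    return out


def layered_effect(seed: int = 0, core_scale: float = 0.25) -> dict:
    """Per-layer pre-post mean changes of every metric on the lesioned phantom."""
    ph = make_phantom(PhantomSpec(seed=seed, lesion_core_scale=core_scale))
    brain = ph.masks["brain"]
    pre_maps = fit_maps(ph.pre, brain)
    post_maps = fit_maps(ph.post, brain)
    mdwi = compute_mdwi(ph.post)
    layers = make_layers(extract_lesion(mdwi, select_cutoff(mdwi, brain), brain))
    report = build_layer_report(pre_maps, post_maps, layers, ph.masks["reference"])
    piv = report.layer_table.pivot_table(
        index=["layer", "metric"], columns="timepoint", values="raw_mean", sort=False
    )
    deltas = {
        (layer, metric): float(piv.loc[(layer, metric), "pre"] - piv.loc[(layer, metric), "post"])
        for layer, metric in piv.index
    }
    return {"deltas": deltas, "report": report}


def null_calibration(n_replicates: int = 200, seed: int = 0,
                     noise_sigma: float = 20.0) -> dict:
    """Fraction of FDR-significant cells on unlesioned noisy replicate phantoms.

    Each replicate simulates an independent pre/post pair with core_scale=1
    (no treatment effect), takes layers from the ground-truth lesion ellipsoid,
    and runs the full layered comparison.  Under the null the expected
    significant fraction is at most alpha; the returned bound adds three
    binomial standard errors.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s % (2**31)) for s in ss.generate_state(n_replicates, dtype=np.uint64)]
    n_sig = 0
    n_cells = 0
    for rep_seed in rep_seeds:
        spec = small_phantom_spec(
            seed=rep_seed, noise_sigma=noise_sigma, lesion_core_scale=1.0
        )
        ph = make_phantom(spec)
        layers = make_layers(ph.masks["lesion"])
        fit_mask = layers.nested_outer | ph.masks["reference"]
        report = build_layer_report(
            fit_maps(ph.pre, fit_mask), fit_maps(ph.post, fit_mask),
            layers, ph.masks["reference"],
        )
        n_sig += int(report.paired_tests["significant"].sum())
        n_cells += len(report.paired_tests)
    frac = n_sig / n_cells
    se = np.sqrt(0.05 * 0.95 / n_cells)
    return {
        "significant_fraction": float(frac),
        "bound": float(0.05 + 3.0 * se),
        "n_cells": n_cells,
    }


def audit_streamlines(streamlines, params: TrackingParams) -> dict:
    """Exhaustive check of the spacing, curvature and length invariants."""
    spacing_bad = curvature_bad = length_bad = 0
    for s in streamlines:
        pts = np.asarray(s.points)
        seg = np.diff(pts, axis=0)
        d = np.linalg.norm(seg, axis=1)
        if np.any(np.abs(d - params.step) > 1e-6):
            spacing_bad += 1
        if len(seg) > 1:
            cosang = np.einsum("ij,ij->i", seg[:-1], seg[1:]) / (d[:-1] * d[1:])
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            if np.any(ang > params.max_turn_angle + 1e-9):
                curvature_bad += 1
        length = streamline_length(pts)
        if length < params.min_length or length > params.max_length + params.step:
            length_bad += 1
    return {
        "n_streamlines": len(streamlines),
        "spacing_violations": spacing_bad,
        "curvature_violations": curvature_bad,
        "length_violations": length_bad,
    }


def disruption_study(seed: int = 0, assay_core_scale: float = 0.05,
                     seeds_per_voxel: int = 2) -> dict:
    """Pre/post tract-continuity counts across a severely ablated core.

    The assay phantom uses a core scale low enough that the post-treatment
    core FA falls below the tracking cutoff across the whole tract
    cross-section, so distal-seeded streamlines stop at the lesion.
    """
    ph = make_phantom(PhantomSpec(seed=seed, lesion_core_scale=assay_core_scale))
    brain = ph.masks["brain"]
    params = TrackingParams()
    seeds = seed_points(ph.masks["distal_seed"], seeds_per_voxel, seed=seed + 1)
    streams = {}
    audits = {}
    for tp, dwi in (("pre", ph.pre), ("post", ph.post)):
        fit = DiffusionTensorModel(dwi, brain).fit()
        streams[tp] = track(seeds, fit, fit.fa(), params)
        audits[tp] = audit_streamlines(streams[tp], params)
    assay = disruption_assay(
        streams["pre"], streams["post"], ph.masks["lesion"],
        ph.masks["distal_seed"], ph.masks["far_target"],
    )
    return {"assay": assay, "audits": audits, "streamlines": streams}
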