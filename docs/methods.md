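# Methods

This note documents the models, numerical choices and open design decisions
behind `fusdwi`, in the order data flows through the package.

## Signal model and acquisition scheme

Diffusion-weighted signals follow the monoexponential Stejskal–Tanner model
S_i = S₀ · exp(−b_i gᵢᵀ D gᵢ) with a symmetric positive-semidefinite tensor
D (mm²/s), b in s/mm². The simulated scheme is one b=0 volume plus 128
directions at b=800 s/mm², matching a typical high-angular single-shell
small-animal protocol. Directions come from a deterministic
spherical-Fibonacci lattice: vendor direction schemes are not published, and
the lattice is reproducible and quasi-uniform (minimum pairwise separation
of the 128 directions exceeds 8°, checked exhaustively).

## The phantom

Geometry (all mm, 1 mm isotropic voxels, identity world transform, voxel
centers at integer indices):

| component | shape | default | tensor (×10⁻³ mm²/s) |
|---|---|---|---|
| grid | box | 64×80×56 | — |
| brain | ellipsoid | semi-axes 26/33/22 at grid center | (0.9, 0.8, 0.7), axes-aligned |
| tract | tube around a circular arc | arc radius 20, tube radius 1, 30°–150° span in the mid-sagittal plane | (1.7, 0.3, 0.3), principal axis tangent |
| reference | sphere | radius 2.5, posterior-inferior of center | (1.7, 0.3, 0.3), principal axis left–right |
| lesion | ellipsoid | semi-axes 4/4/6 at the tract apex | suppressed (below) |

The brain size is piglet-scale; the tract arc emulates the C-shape of the
fornix with a curvature radius (20 mm) far above the tracking bound; the
reference sphere emulates the splenium of the corpus callosum (dense,
coherent, left–right fibers) and sits away from both tract and lesion. The
lesion volume, (4/3)π·4·4·6 ≈ 402 mm³, sits inside the 302–432 mm³ range of
the published per-animal measurements and is roughly four times the
83.78 mm³ sonication cell, as observed in vivo. Tissue eigenvalues give
tract FA ≈ 0.80 (dense white matter) and background FA ≈ 0.12, below the
0.15 tracking cutoff so streamlines cannot wander out of the tract.

### Lesion effect

At normalized ellipsoidal radius r the scale factor is the linear profile
s(r) = c + (1−c)·min(r, 1) with core scale c, reproducing the observed
pattern of maximal change at the core decaying radially (the same layering
seen in thermometry contours). The post-treatment eigenvalues are

    λᵢ′ = s · λ̄ · (λᵢ / λ̄)^(s²),   λ̄ = (λ₁+λ₂+λ₃)/3.

The first factor scales the tensor magnitude; the exponent shrinks
eigenvalue *ratios* toward 1. Both effects vanish continuously at the rim
(s=1). This models coagulative necrosis as simultaneously restricting
diffusion and destroying the oriented axonal substrate: a pure magnitude
scaling would leave FA exactly invariant, which contradicts the in-vivo
observation that FA falls along with the diffusivities. With this model all
five metrics (ADC, AD, RD, MD, FA) decrease monotonically as s decreases;
for strongly anisotropic voxels at intermediate s the shrinkage can slightly
raise λ₂, λ₃ before the magnitude factor wins — layer means still decrease,
and the MDWI-hyperintensity invariant (post ≥ pre at every lesion voxel) is
asserted in the tests. When shrinkage reorders eigenvalues they are re-sorted
to keep the descending convention.

The in-vivo effect magnitudes were published only graphically, so the core
scale is a free parameter. The default c = 0.25 produces a severe core
(MD −28%) with clearly layered falloff. The tract-disruption assay uses
c = 0.05, low enough that post-treatment core FA falls below the 0.15
tracking cutoff across the whole tract cross-section; at milder suppression
the sub-cutoff zone is narrower than the tract and streamlines skirt it.

### Noise

Rician magnitude noise: |S + n₁ + i·n₂| with independent N(0, σ²) channels,
drawn from two `SeedSequence` children of the spec seed (pre and post are
independent realizations; identical specs are bit-reproducible). Noise is
applied inside the brain mask only — all analyses are brain-masked, and
skipping the empty exterior saves memory. "SNR 50" in the tests means
S₀/σ = 1000/20. Not emulated: susceptibility/eddy distortion, motion,
multi-shell schemes, partial-volume mixing at tissue borders, temperature
fields. Passing tests therefore validate the analysis chain, not robustness
to those real-world artifacts.

## Tensor fitting and metrics

Ordinary log-linear least squares per voxel (pseudoinverse of the shared
129×7 design matrix applied to ln S), requiring ≥1 b=0 and ≥6 DW volumes.
Voxels with any nonpositive intensity are marked invalid rather than clipped
(the log is undefined and clipping biases). Negative eigenvalues after
decomposition are clamped to 0 and the clamped-voxel count is reported. On
noiseless phantom signals the system is consistent and recovery is exact to
~10⁻¹³ relative. Weighted/iterative estimators (WLS, RESTORE) are out of
scope.

ADC is computed from the mean DW signal, ADC = −(1/b)·ln(S̄_dw/S̄₀), not from
the tensor trace: averaging signals before the log weights the directional
decays differently, so ADC and MD are genuinely distinct maps and
ADC ≤ MD for anisotropic voxels (signal-averaging convexity, asserted on the
phantom up to the small non-uniformity of the direction lattice). MDWI is
the mean over all volumes including b=0.

## Lesion segmentation

The cutoff is the smallest intensity present in the brain such that fewer
than 1.1% of brain voxels exceed it (fraction configurable). The original
inflection-point criterion behind the 1.1% figure is not reproducibly
specified, so the fixed-fraction rule is the implemented primitive. The
lesion is the 26-connected supra-cutoff component containing the global
maximum (26-connectivity captures the diagonal contiguity of a smooth blob;
maximum ties break at the lowest linear index). Layers use one iteration of
6-connected erosion/dilation — the face-adjacent structuring element best
approximates a 1 mm radial peel at 1 mm voxels. On the noiseless default
phantom the segmented region is the lesion plus the supra-background tract
rim; the volume error (≈146 mm³) stays within the one-surface-voxel-layer
tolerance (200 mm³), and Dice against the generator truth is ≈0.88 noiseless
and ≈0.82 at SNR 50.

## Layered statistics

Reported per (timepoint, layer, metric): raw mean, reference mean from the
matching timepoint, and normalized percent (100·raw/ref). The analysis
layers default to the disjoint shells (core, boundary shell, outer shell);
the nested interpretation (core ⊆ region ⊆ dilation) is available via a
flag, since either reading is defensible.

Paired pre/post tests pair voxels within each layer. One phantom is one
subject, so voxel pairing is the testable surrogate for the original
animal-level pairing; with several subjects, pair per-subject means via
`paired_t_test` directly. The paired tests use **raw** voxel values:
dividing each timepoint by its own noisy reference mean would inject a
shared offset into every pair and destroy type-I-error calibration (measured
false-positive fraction ≈0.25 instead of ≤0.05), whereas for animal-level
pairing normalization is part of the measurement. All-zero differences give
t=0, p=1 by convention; zero-variance nonzero differences raise a degenerate
error. The FDR family is the 15 (metric × layer) cells, Benjamini–Hochberg,
α = 0.05 two-sided. Calibration is verified on 200 unlesioned noisy
replicates (reduced 28×36×26 grid, same tissue classes and 129-volume
scheme, layers taken from the ground-truth lesion ellipsoid), requiring the
significant fraction ≤ 0.05 + 3 binomial SE; measured ≈0.01. One-way ANOVA
across the three layers (per metric, per timepoint, raw values) with Tukey
HSD post-hoc completes the report. Mixed-effects models and power analysis
are out of scope.

## Tractography

Deterministic single-tensor tracking: bidirectional Euler integration along
the principal eigenvector of the component-wise trilinearly interpolated
tensor (smoother than nearest-neighbor eigenvector lookup and well defined
at voxel boundaries), sign-aligned with the previous step. Defaults: 0.1 mm
step, 1 mm minimum curvature radius enforced as a per-step turning-angle cap
2·arcsin(step/2R) (the exact discrete analogue of a circular arc), 5 mm
minimum and 250 mm maximum length with the cap split between the two halves.
Termination: grid exit, length cap, curvature cap, or interpolated FA below
0.15 — the new point is then *not* appended, so streamlines stop at a
low-FA face and never enter it. The 0.15 figure is conventionally an
orientation-distribution amplitude cutoff; FA is the natural single-tensor
analogue and the value is configurable. Seeds in sub-cutoff voxels produce
no streamline; seed jitter is uniform within the voxel and seeded.

The disruption assay seeds a distal tract segment (fimbria analogue),
tracks pre and post, and counts streamlines reaching the far end of the
arc and entering the lesion. Pre-treatment most seeds reach the target;
post-treatment (assay core scale) none do — the single-tensor analogue of
tracts stopping at the lesion.

## Problem sizes and determinism

Default studies: 64×80×56 grid (≈79k brain voxels), 129 volumes; replicate
null studies use the reduced 28×36×26 grid, 200 replicates. The pipeline
expands one global seed into per-stage substreams with
`numpy.random.SeedSequence`, records every stage's seed and configuration in
JSON sidecars, and reruns byte-identically. All stored seeds stay below 2³¹.

## Known limitations

* The phantom's discrete-valued background makes the intensity histogram
  less continuous than real tissue; the fixed-fraction cutoff consequently
  lands at the background/tract intensity boundary rather than at a true
  histogram inflection.
* The segmented region deliberately includes the bright tract rim adjacent
  to the lesion (real MDWI segmentations share this white-matter
  partial-inclusion behavior); Dice and volume tolerances account for it.
* Voxel-level pairing overstates the effective sample size relative to an
  animal-level analysis; its p-values demonstrate calibration and direction,
  not in-vivo effect sizes.
* The tracker is single-tensor: crossing fibers, orientation-distribution
  models and probabilistic tracking are explicitly out of scope.
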