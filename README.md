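# fusdwi — acute MRgFUS lesion assessment from diffusion-weighted MRI

Magnetic resonance–guided focused ultrasound (MRgFUS) creates a thermal
ablation lesion without opening the skull. Within the first hour the lesion
is hard to characterize on conventional anatomical MRI, but diffusion MRI
sees it directly: coagulative necrosis restricts water diffusion, so the
lesion lights up on the **mean diffusion-weighted image** (MDWI, the
voxel-wise average of all DWI volumes including b=0) and every tensor-derived
metric drops. `fusdwi` packages that whole assessment chain — for imaging
scientists who want a tested, reproducible reference implementation, and as a
fully synthetic test bed when no acquisition is at hand:

* **Phantom simulation** — seeded pre/post-ablation DWI pairs of a
  small-animal brain (1 mm isotropic, one b=0 + 128 directions at
  b=800 s/mm²) with an anisotropic fornix-like tract, a splenium-like
  reference region, and an ellipsoidal lesion whose diffusivity suppression
  peaks at the core and decays radially. Rician noise, bit-reproducible from
  the seed.
* **Tensor metrics** — per-voxel log-linear tensor fit
  (ln Sᵢ = ln S₀ − bᵢ gᵢᵀ D gᵢ) with eigenvalue maps and the scalar metrics
  FA, MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2, plus ADC from the mean DW
  signal and the MDWI itself.
* **Lesion segmentation** — voxel-fraction cutoff intensity (the smallest
  intensity exceeded by <1.1% of brain voxels), 26-connected component
  containing the global maximum, then one-voxel erosion/dilation to produce
  the lesion **core**, **boundary shell**, and **outer shell** layers, with
  volume reports.
* **Layered statistics** — per-layer metric means, percent normalization to
  the reference region, paired pre/post t-tests with Benjamini–Hochberg FDR
  over the 15 (metric × layer) cells, one-way ANOVA across layers with Tukey
  HSD post-hoc.
* **Tractography** — deterministic single-tensor streamline tracking
  (0.1 mm steps, 1 mm minimum curvature radius, FA 0.15 termination, 5 mm
  minimum length) and a tract-disruption assay counting distal-seeded
  streamlines that still reach a far target after ablation.

## Worked example

```python
import fusdwi

# simulate one treated animal (noiseless here, for exact numbers)
phantom = fusdwi.make_phantom(fusdwi.PhantomSpec(seed=3))
brain = phantom.masks["brain"]

# fit tensors and build all six scalar maps per timepoint
maps = {}
for tp, dwi in (("pre", phantom.pre), ("post", phantom.post)):
    fit = fusdwi.DiffusionTensorModel(dwi, brain).fit()
    m = fit.scalar_maps()
    m["ADC"] = fusdwi.compute_adc(dwi)
    m["MDWI"] = fusdwi.compute_mdwi(dwi)
    maps[tp] = m

# segment the lesion on the post-treatment MDWI and layer it
mdwi = maps["post"]["MDWI"]
cutoff = fusdwi.select_cutoff(mdwi, brain, fraction=0.011)
layers = fusdwi.make_layers(fusdwi.extract_lesion(mdwi, cutoff, brain))
print(f"cutoff {cutoff:.1f}, lesion region "
      f"{fusdwi.mask_volume(layers.region, 1.0):.0f} mm^3")

# layered pre/post comparison
report = fusdwi.build_layer_report(
    maps["pre"], maps["post"], layers, phantom.masks["reference"])
print(report.summary())
```

This prints (abridged):

```
cutoff 531.4, lesion region 548 mm^3
Lesion layer analysis

Normalized means (% of reference):
timepoint           pre    post
layer    metric
core     ADC     112.14   81.07
         AD       58.52   37.53
         RD      232.20  178.90
         MD      103.83   74.41
         FA       25.58   13.45
boundary ADC     108.48  104.92
...
Paired pre/post tests: 10/15 significant (BH-FDR, alpha=0.05)
Layer ANOVAs: 10/10 significant
```

Reading the numbers: the segmented region (548 mm³) brackets the true
402 mm³ ellipsoid plus the bright tract rim; in the core every metric falls
sharply after treatment (e.g. MD from 103.8% to 74.4% of the reference
value), the boundary shell falls less, and the outer shell — outside the
lesion — is untouched, reproducing the radially decaying damage pattern.
The 10 significant paired cells are exactly the core and boundary rows.

The same run is available from the shell:

```sh
fusdwi run-all --seed 3 --out-dir out/
```

which writes NIfTI volumes and masks, TSV reports, TRK/text streamlines and
JSON provenance sidecars.

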