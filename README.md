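# nirquant

Quantification pipeline for **planar near-infrared (NIR) fluorescence imaging
of tumor-bearing mice**, of the kind produced by filter-based whole-animal
imagers (710 nm excitation / 790 nm emission): threshold-derived regions of
interest, hip-reference luminosity normalization, autofluorescence-weighted
signal-to-noise statistics per organ and timepoint, cumulative pixel
histograms, white-field/fluorescence composite overlays, and ex vivo
lung-node localization scoring. A synthetic mouse-phantom generator with
fully known ground truth stands in for animal images, so every step of the
quantification can be validated against the parameters that generated the
data.

It is intended for imaging scientists who analyze planar (non-tomographic)
NIR biodistribution experiments — targeted nanoparticle contrast agents,
antibody conjugates, quantum-dot micelles — and want a statistic that is
comparable across animals and timepoints despite exposure and positioning
differences.

## The statistic

Planar NIR frames have arbitrary, drifting intensity scales. The pipeline
therefore works entirely in normalized units:

1. **Hip normalization.** Each image is rescaled by `f = R / mean(hip ROI)`
   so that a reference patch over the hip — tissue that takes up no contrast
   agent — lands at a fixed level `R` (default 100). Every downstream number
   is invariant to global luminosity changes by construction.
2. **Autofluorescence** `A` is the intrinsic tissue level, estimated from a
   pre-injection or uninjected control (mean over the body after hip
   normalization) or, as a fallback, identified with the hip level itself.
3. **Background** is sampled from an annulus near each ROI (Chebyshev
   distance `r_in < d ≤ r_out`, default 3–10 px), restricted to the body
   interior and excluding all other ROIs: the "scattered light" from internal
   organs near the ROI.
4. **Normalized SNR** per ROI:

   ```
   SNR = (mean_ROI − A) / SD(background)          (noise_sd mode, default)
   SNR = (mean_ROI − A) / (mean_background − A)   (mean_ratio mode)
   ```

   An ROI containing only autofluorescence scores exactly 0; values are
   signed and never clipped. Cohort tables report mean ± SD over N animals.

For excised lungs bearing melanoma nodes, the **localization index**
`(mean over node rims − A) / (mean over remaining lung − A)` distinguishes
diffuse signal (index ≈ 1) from node-localized signal (index ≫ 1).

## Worked example

Generate a default phantom cohort (5 animals, imaged 1/2/4 h post-injection)
and quantify it:

```python
import numpy as np
from nirquant import *

truth = PhantomTruth()                      # default mouse phantom
frames = generate_cohort(truth, 5, [1.0, 2.0, 4.0], seed=42)
table = biodistribution(frames)
print(table.summary.to_string(index=False))
```

```
roi_name  timepoint_h  mean_snr   sd_snr  n
  kidney          1.0  7.149279 4.872620  5
  kidney          2.0  8.082885 5.508787  5
  kidney          4.0  7.991468 5.475121  5
   liver          1.0  1.713540 0.441210  5
   liver          2.0  1.517577 0.388344  5
   liver          4.0  1.337965 0.341315  5
    lung          1.0  6.948226 0.770230  5
    lung          2.0  6.329023 0.714978  5
    lung          4.0  5.696838 0.660384  5
  muscle          1.0  1.575645 0.388484  5
  muscle          2.0  1.616909 0.391207  5
  muscle          4.0  1.663598 0.390781  5
  spleen          1.0  1.522153 0.469915  5
  spleen          2.0  1.346097 0.415094  5
  spleen          4.0  1.183717 0.364038  5
   tumor          1.0 17.397915 2.102413  5
   tumor          2.0 16.851367 2.509915  5
   tumor          4.0 16.915627 2.465251  5
```

The tumor SNR is the highest among solid-tissue ROIs, essentially flat from
1 h to 4 h (the default tumor kinetics are on their uptake plateau), the
liver is lowest, and the kidney is bright but highly variable between
animals — the qualitative biodistribution pattern of a tumor-targeted
nanoparticle agent with renal signal. Comparing the tumor and body pixel
distributions on the hip-normalized image:

```python
img, regs = generate_phantom(truth, 1.0)
normed, f = hip_normalize(img, hip_reference_roi(regs))   # f = 20.020 here
body, tumor = regs.body_mask, regs.mask("tumor")
edges = np.histogram_bin_edges(normed.pixels[body], bins=64)
print(distribution_contrast(
    cumulative_histogram(normed, tumor, bin_edges=edges),
    cumulative_histogram(normed, body & ~tumor, bin_edges=edges)))
```

```
{'mean_ratio': 5.79452462446824, 'sd_ratio': 0.28308602860675364, 'separable': True}
```

The tumor ROI is ~5.8× brighter than the rest of the body and its pixel
distribution is much narrower (`sd_ratio < 1`), so the tumor separates
cleanly in the cumulative histograms.

A command-line interface wraps the same library:

```sh
nirquant simulate --subjects 5 --timepoints 1,2,4 --seed 42 --out cohort/
nirquant segment  --image cohort/m1_t1h.tif --method otsu --out mask
nirquant quantify --manifest cohort/manifest.csv --out results/
nirquant report   --results results/ --out report/
```

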