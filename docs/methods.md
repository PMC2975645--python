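# Methods

## The quantification model

Planar NIR fluorescence images carry linear intensities in arbitrary units
that drift with exposure, working distance and animal positioning. The
pipeline makes three modeling commitments:

1. **Global luminosity is multiplicative.** A hip reference ROI — tissue with
   no specific agent uptake — is driven to a fixed level `R` by rescaling the
   whole image (`f = R / mean(hip)`). Normalization by a single global factor
   is the only correction consistent with compensating "overall image
   luminosity": it removes exposure and gain differences exactly and leaves
   every intensity *ratio* untouched. `R = 100` is arbitrary; all SNR outputs
   are invariant to it, and "net intensity" outputs are reported in units of
   `R`.

2. **Autofluorescence is a baseline, removed by subtraction.** The intrinsic
   tissue level `A` (from a pre-injection/uninjected control, or the hip
   level as a documented fallback) is subtracted from ROI means, so an ROI
   containing no agent scores exactly 0. Weighting by division was the
   alternative reading; subtraction was chosen precisely for that zero point.

3. **"Noise" is the scattered light near the ROI.** The background annulus
   (Chebyshev ring at 3–10 px from the ROI by default, inside the body and
   excluding all other named ROIs) samples the diffuse light scattered from
   internal organs. The default SNR divides by the annulus SD — reading
   "background noise" as a fluctuation scale; a `mean_ratio` mode dividing by
   the annulus excess mean is provided as a first-class alternative since the
   field uses both conventions. The two modes order isolated, comparably
   surrounded ROIs identically, but can legitimately disagree on dim organs
   whose annuli are contaminated differently by neighboring organs' scattered
   light.

   The annulus additionally avoids a band of width `body_edge_margin`
   (default 8 px ≈ 3.6 blur widths) inside the body outline: the intensity
   falloff at the silhouette edge is a boundary artifact of planar imaging,
   not scattered light from internal organs, and including it would both
   inflate the SD mode and drive the mean mode negative for edge-adjacent
   ROIs.

Pixel statistics use the population SD (the pixels are the whole population
of the ROI); cohort summaries use the sample SD across the N animals.
Negative SNRs are reported unclipped, and a frame or ROI whose quantification
fails is dropped from the table with a logged reason rather than imputed.

## ROI determination

ROIs are found by threshold analysis. When a second, skin-removed reference
frame is available, the working image is the pixelwise **minimum** of the two:
a candidate pixel must be bright in both frames, which suppresses
skin-scatter and motion artifacts present in only one. (The comparison
operator is a design choice; minimum is the weakest conjunction that keeps
the semantics "supported by both images".) Thresholding is Otsu's method
within the body mask by default, with a quantile mode for explicit control;
pixels exactly at the threshold are excluded, so a constant image yields an
empty detection rather than a whole-body ROI. Components are 8-connected and
components under `min_area = 25 px` are discarded — small bright specks from
incompletely removed hair are artifacts, not ROIs. Seeded detection (a named
point per expected region) assigns components to region names; unseeded
detection ranks components by mean intensity. Organ ROIs on real data are
expected to be user-annotated; detection is aimed at bright tumor-like
regions. One RegionSet may be reused across timepoints or re-detected per
image; the pipeline does not force either choice.

## The synthetic phantom

No animal images accompany this kind of study, so the package ships a
generative phantom whose parameters are the ground truth for every test.
The model is the minimal one under which each quantification step has a
recoverable target:

```
I = L · ( A0 · body + Σ_r c_r(t) · shape_r )  ⊛  Gaussian(σ)   + noise
c_r(t) = c_max,r · (1 − e^(−k_in·t)) · e^(−k_out·t)
```

- `A0` — uniform body autofluorescence (5 intensity units).
- `L` — per-image luminosity factor; lognormal across images (σ_log = 0.2),
  the nuisance hip normalization removes.
- Mono-exponential uptake/washout per region. Tumor `k_in = 3/h,
  k_out = 0.02/h` puts the tumor on a plateau across the 1–4 h imaging
  window (≈1 % change), matching targeted agents that accumulate within the
  first hour and persist.
- `σ = 2.2 px` Gaussian blur stands in for tissue scattering; the organ
  "scattered light" sampled by the annuli is exactly the tail of this blur.
- Noise: Poisson shot noise at 20 000 counts per intensity unit plus 0.01
  units of Gaussian read noise — a well-exposed cooled-CCD acquisition in
  which photon noise sits well below the scattered-light structure of the
  background. (Negative read-noise excursions are clipped at zero; at these
  settings clipping never occurs in practice.)

Default anatomy (128×128 side view): a large flank tumor (14×16 px
half-axes), liver, kidney, spleen, lung, a muscle patch, and a 4 px hip
reference placed so that no organ's scattered light reaches it. The tumor's
fluorescent extent reaches 2 px beyond its anatomical ROI (`halo_px`): agent
accumulating in the infiltrative margin fluoresces outside the palpable core
that defines the ROI. This is what gives the tumor ROI a plateau-dominated,
narrow pixel distribution while the intensity ramp falls in the surrounding
body — the contrast structure real tumor composites show — and it is the
reason threshold detection slightly over-segments the ROI (Jaccard ≈ 0.77
rather than ≈ 1).

Cohorts add per-subject variability: region centers jitter by ±2 px (clamped
to keep the geometry valid), and each region's amplitude is scaled by a
mean-one lognormal factor per subject — 7 % for most tissues, 45 % for the
kidney, whose clearance-driven signal varies widely between animals. Subject
and frame seeds derive from a single `SeedSequence`, so cohorts are
byte-reproducible.

Ex vivo lung phantoms (96×96, two elliptical lobes) carry `node_count = 8`
melanoma nodes of radius 3 px placed randomly with non-overlapping
node+rim footprints. The *diffuse* stage is a uniform `diffuse_level = 8`
over the lung (the ex vivo dose is one tenth of the in vivo dose, hence the
low level); the *localized* stage drops the diffuse component to 0.3× and
adds `rim_amplitude = 20` in a 2 px ring around each node, with only
`node_core_level = 2` in the cores — antibody-targeted particles decorate
the periphery of a cell cluster rather than penetrating it. No blur is
applied ex vivo (excised organs are imaged in contact, without the
depth-scattering of whole-body views).

### What the phantom does and does not emulate

It reproduces: multiplicative luminosity drift, diffuse autofluorescence,
organ scattered light, plateau tumor kinetics, between-animal uptake
scatter, shot/read noise, and the diffuse-versus-localized ex vivo contrast.
It does **not** simulate photon transport, depth-dependent attenuation, 3-D
anatomy projected to 2-D, heterogeneous autofluorescence (gut contents,
skin), motion, or camera calibration. Tests passing on the phantom therefore
show the *pipeline arithmetic* is correct and unbiased under the stated
noise model — not that the statistic is robust to every artifact of real
animal images. Hair specks (bright out-of-ROI artifacts) are supported but
off by default.

## Numerical choices

- Masks are hard pixel sets (a pixel is in or out); all geometry is 0-based,
  row-major. Annuli and dilations use Chebyshev (chessboard) distance, so a
  1 px ring around a pixel is its 8 neighbors.
- The blur uses a truncated (4σ), normalized Gaussian kernel with zero
  padding; with the body kept ≥4σ from the frame edge, total intensity is
  conserved to well below 0.1 %.
- The `mean_ratio` SNR floors its denominator at `1e-9·R` to keep the value
  finite when the background excess is ≈ 0.
- Histograms default to 64 bins over the pooled range of the compared masks
  and are computed on hip-normalized images (the normalized scale is the
  comparable one); cumulative frequencies are exact integer counts divided
  by n.
- Reports are deterministic: fixed file names, sorted JSON keys, fixed CSV
  float format — two runs on identical inputs are byte-identical.
- TIFF round trips are exact for 16-bit integer data and for float data
  representable in float32; metadata travels in a JSON sidecar, not in
  vendor TIFF tags.

## Validation design

Test sizes were chosen to exercise each property at the smallest scale where
it is meaningful: 32×32 phantoms for the convolution oracle, 200 random
≤64×64 image/mask pairs for pixel-statistic oracle agreement, and 20 cohorts
of 5 subjects × 3 timepoints for recovery. The noise-recovery check compares
noisy cohorts against the *same* cohorts regenerated with noise disabled
(identical sub-seeds, hence identical geometry, luminosity and uptake
draws), isolating the bias attributable to measurement noise from the
deliberate between-animal variability.

## Known limitations

- The SNR's `noise_sd` denominator needs genuine scattered-light structure
  in the annulus; in a nearly structure-free background (very small blur, or
  an isolated ROI in a flat field) the statistic is ill-conditioned, and the
  degenerate case (SD exactly 0) raises an error instructing the user to
  widen the annulus.
- A single label map cannot express overlapping ROIs; overlapping derived
  regions (body, annuli) are carried as auxiliary masks.
- The "periphery of the lungs" component of ex vivo signal is not separately
  scored; it contributes only to the lung coefficient of variation.
- Acquisition bit depth and any vendor gamma correction are unknown for
  filter-wheel imagers generally; the pipeline assumes linear intensities
  and 16-bit/float TIFF storage as conventions.
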