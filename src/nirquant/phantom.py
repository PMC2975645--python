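"""Synthetic planar NIR mouse phantoms with known ground truth.

The generative model is deliberately the minimal one under which every step of
the quantification pipeline has a recoverable truth:

* additive region amplitudes: ``I0 = L * (A0 * body + sum_r c_r(t) * shape_r)``
  where ``A0`` is a uniform body autofluorescence, ``L`` a per-image global
  luminosity factor (what hip normalization is meant to remove), and ``c_r(t)``
  a mono-exponential uptake/washout curve per region;
* a Gaussian point-spread blur standing in for tissue scattering of the NIR
  light ("scattered light" around organs is the tail of this blur);
* Poisson shot noise (``poisson_gain`` counts per intensity unit) plus
  Gaussian read noise.

Defaults describe the study conditions: a side view of a mouse bearing a
flank tumor, with liver, kidney, spleen, lung and a muscle patch, a hip
reference patch that takes up no agent, imaging at 1/2/4 h post-injection,
cohorts of N=5 animals. Tumor kinetics (k_in = 3/h, k_out = 0.02/h) put the
tumor signal on a plateau over the 1-4 h imaging window; the kidney is bright,
the liver dim. Amplitudes are configuration defaults, not claims about any
real agent. Noise defaults correspond to a well-exposed cooled-CCD
acquisition in which scattered-light structure, not photon noise, dominates
the background.

Ex vivo lung phantoms emulate excised lungs bearing small melanoma nodes:
either a diffuse stage (agent still washing through: uniform signal over the
lung) or a localized stage (agent retained in a bright rim around each node
while the diffuse component has washed out).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, ValidationError
from .imaging_io import ImageMeta, NIRImage, RegionSet

__all__ = [
    "NoiseModel",
    "RegionSpec",
    "PhantomTruth",
    "LungPhantomTruth",
    "CohortVariation",
    "uptake_kinetics",
    "generate_phantom",
    "generate_cohort",
    "generate_lung_exvivo",
]


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def uptake_kinetics(c_max: float, k_in: float, k_out: float, t: float) -> float:
    """Region amplitude at time ``t`` hours post-injection.

    ``c_max * (1 - exp(-k_in * t)) * exp(-k_out * t)``: zero at injection,
    never exceeding ``c_max``, rising with rate ``k_in`` (1/h) and washing out
    with rate ``k_out`` (1/h).
    """
    for name, v in (("c_max", c_max), ("k_in", k_in), ("k_out", k_out), ("t", t)):
        if not v >= 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    if t == 0:
        return 0.0
    rise = 1.0 - math.exp(-k_in * t) if math.isfinite(k_in) else 1.0
    return c_max * rise * math.exp(-k_out * t)


# ---------------------------------------------------------------------------
# truth dataclasses
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Poisson shot noise at ``poisson_gain`` counts per intensity unit, plus
    zero-mean Gaussian read noise of SD ``read_sigma`` intensity units. Either
    component is disabled by setting its parameter to 0."""

    poisson_gain: float = 20000.0
    read_sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.poisson_gain < 0 or self.read_sigma < 0:
            raise ValidationError("noise parameters must be >= 0")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(poisson_gain=0.0, read_sigma=0.0)

    @property
    def enabled(self) -> bool:
        return self.poisson_gain > 0 or self.read_sigma > 0


@dataclass
class RegionSpec:
    """Geometry + kinetics of one phantom region (disc or axis-aligned ellipse).

    ``halo_px`` lets the fluorescent extent reach beyond the anatomical region
    that defines the ROI mask: agent accumulating in a tumor's infiltrative
    margin fluoresces outside the palpable core. The ROI mask stays at
    ``radii``; the emitted intensity fills ``radii + halo_px``.
    """

    name: str
    kind: Literal["disc", "ellipse"]
    center: tuple[float, float]  # (row, col), pixels
    radii: tuple[float, float]   # (r_row, r_col); equal for a disc
    c_max: float = 0.0           # peak amplitude, arbitrary intensity units
    k_in: float = 2.0            # 1/h
    k_out: float = 0.1           # 1/h
    halo_px: float = 0.0         # fluorescent margin beyond the ROI

    def __post_init__(self) -> None:
        if self.c_max < 0 or self.k_in < 0 or self.k_out < 0:
            raise ValidationError(f"region {self.name!r}: negative parameter")
        if min(self.radii) <= 0:
            raise ValidationError(f"region {self.name!r}: radii must be > 0")
        if self.halo_px < 0:
            raise ValidationError(f"region {self.name!r}: halo_px must be >= 0")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return _ellipse_mask(shape, self.center, self.radii)

    def emission_mask(self, shape: tuple[int, int]) -> np.ndarray:
        radii = (self.radii[0] + self.halo_px, self.radii[1] + self.halo_px)
        return _ellipse_mask(shape, self.center, radii)

    def shifted(self, dr: float, dc: float) -> "RegionSpec":
        return dataclasses.replace(
            self, center=(self.center[0] + dr, self.center[1] + dc)
        )


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center
    a, b = radii
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def _default_regions() -> list[RegionSpec]:
    # Side view, 128x128; amplitudes in units of the autofluorescence scale.
    # The flank tumor is a prominent ~2-week xenograft: large relative to the
    # scattering blur, so its ROI is plateau-dominated, and placed so its
    # scattered-light annulus clears the abdominal organs; the hip patch takes
    # up no agent.
    return [
        RegionSpec("tumor", "ellipse", (58, 88), (14, 16), c_max=55.0, k_in=3.0, k_out=0.02, halo_px=2.0),
        RegionSpec("liver", "ellipse", (60, 42), (8, 9), c_max=10.0, k_in=2.0, k_out=0.1),
        RegionSpec("kidney", "disc", (74, 56), (6, 6), c_max=55.0, k_in=1.5, k_out=0.05),
        RegionSpec("spleen", "ellipse", (84, 46), (4, 6), c_max=15.0, k_in=2.0, k_out=0.1),
        RegionSpec("lung", "ellipse", (48, 36), (5, 6), c_max=12.0, k_in=2.5, k_out=0.15),
        RegionSpec("muscle", "disc", (64, 22), (5, 5), c_max=3.0, k_in=2.0, k_out=0.1),
        RegionSpec("hip_ref", "disc", (84, 76), (4, 4), c_max=0.0, k_in=0.0, k_out=0.0),
    ]


@dataclass
class PhantomTruth:
    """Full generative parameter set for one in vivo phantom image/cohort."""

    image_shape: tuple[int, int] = (128, 128)
    body_center: tuple[float, float] = (64.0, 64.0)
    body_radii: tuple[float, float] = (30.0, 52.0)  # (row, col) semi-axes
    regions: list[RegionSpec] = field(default_factory=_default_regions)
    autofluorescence: float = 5.0  # A0, uniform over the body
    luminosity: float = 1.0        # L, global multiplicative factor
    psf_sigma: float = 2.2         # scattering blur, pixels
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.autofluorescence < 0 or self.luminosity < 0 or self.psf_sigma < 0:
            raise ValidationError("A0, L, psf_sigma must all be >= 0")
        self.validate_geometry()

    # -- geometry --------------------------------------------------------
    def body_mask(self) -> np.ndarray:
        return _ellipse_mask(self.image_shape, self.body_center, self.body_radii)

    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def validate_geometry(self) -> None:
        body = self.body_mask()
        masks = {}
        for r in self.regions:
            m = r.mask(self.image_shape)
            if not m.any():
                raise GeometryError(f"region {r.name!r} covers no pixels")
            if np.any(r.emission_mask(self.image_shape) & ~body):
                raise GeometryError(f"region {r.name!r} extends outside the body")
            masks[r.name] = m
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(masks[a] & masks[b]):
                    raise GeometryError(f"regions {a!r} and {b!r} overlap")

    # -- derived variants ------------------------------------------------
    def with_noise_off(self) -> "PhantomTruth":
        return dataclasses.replace(self, noise=NoiseModel.off())

    def with_tumor_amplitude(self, c_max: float) -> "PhantomTruth":
        regions = [
            dataclasses.replace(r, c_max=c_max) if r.name == "tumor" else r
            for r in self.regions
        ]
        return dataclasses.replace(self, regions=regions)

    # -- (de)serialization ----------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomTruth":
        doc = yaml.safe_load(Path(path).read_text())
        doc["regions"] = [RegionSpec(**{**r, "center": tuple(r["center"]),
                                        "radii": tuple(r["radii"])})
                          for r in doc.get("regions", [])]
        doc["noise"] = NoiseModel(**doc.get("noise", {}))
        for key in ("image_shape", "body_center", "body_radii"):
            doc[key] = tuple(doc[key])
        return cls(**doc)


# ---------------------------------------------------------------------------
# in vivo generation
# ---------------------------------------------------------------------------

def _blur(clean: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return clean
    return gaussian_filter(clean, sigma, mode="constant", cval=0.0, truncate=4.0)


def _apply_noise(clean: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    out = clean
    if noise.poisson_gain > 0:
        out = rng.poisson(noise.poisson_gain * out).astype(np.float64)
        out /= noise.poisson_gain
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    # A cooled CCD never reports negative counts after baseline subtraction.
    return np.maximum(out, 0.0)


def clean_field(truth: PhantomTruth, t: float) -> np.ndarray:
    """Noise-free, PSF-blurred intensity field at time ``t`` (hours)."""
    body = truth.body_mask()
    pre = truth.autofluorescence * body.astype(np.float64)
    for r in truth.regions:
        amp = uptake_kinetics(r.c_max, r.k_in, r.k_out, t)
        if amp > 0:
            pre += amp * r.emission_mask(truth.image_shape)
    pre *= truth.luminosity
    return _blur(pre, truth.psf_sigma)


def _truth_regions(truth: PhantomTruth) -> RegionSet:
    lm = np.zeros(truth.image_shape, dtype=np.int32)
    names = {}
    for i, r in enumerate(truth.regions, start=1):
        lm[r.mask(truth.image_shape)] = i
        names[i] = r.name
    return RegionSet(lm, names, aux_masks={"body": truth.body_mask()})


def generate_phantom(
    truth: PhantomTruth,
    t: float,
    subject_id: str = "phantom",
    view: str = "side",
) -> tuple[NIRImage, RegionSet]:
    """One synthetic frame at ``t`` hours post-injection + its ground-truth regions.

    Deterministic under a fixed ``truth`` (including its seed).
    """
    clean = clean_field(truth, t)
    rng = np.random.default_rng(truth.seed)
    px = _apply_noise(clean, truth.noise, rng)
    img = NIRImage(px, meta=ImageMeta(subject_id=subject_id, timepoint_h=t, view=view))
    return img, _truth_regions(truth)


@dataclass
class CohortVariation:
    """Per-subject/per-image variability in a generated cohort.

    Luminosity varies per image (lognormal with ``sigma_log`` on top of the
    base L) — this is exactly the nuisance hip normalization removes. Region
    centers are jittered per subject by up to ``center_jitter_px`` pixels to
    emulate animal-to-animal anatomy and posing differences. Per-subject
    uptake varies as a mean-one lognormal factor on each region's ``c_max``
    (``amplitude_sigma_log``, with per-region overrides): tumor uptake varies
    a few percent between animals while renal clearance varies widely.
    """

    luminosity_sigma_log: float = 0.2
    center_jitter_px: int = 2
    amplitude_sigma_log: float = 0.07
    amplitude_sigma_log_overrides: dict[str, float] = field(
        default_factory=lambda: {"kidney": 0.45}
    )

    def amplitude_sigma(self, region_name: str) -> float:
        return self.amplitude_sigma_log_overrides.get(
            region_name, self.amplitude_sigma_log
        )


def _jitter_regions(truth: PhantomTruth, rng: np.random.Generator,
                    jitter: int) -> PhantomTruth:
    if jitter <= 0:
        return truth
    regions: list[RegionSpec] = []
    for i, r in enumerate(truth.regions):
        dr, dc = (int(v) for v in rng.integers(-jitter, jitter + 1, size=2))
        cand = r.shifted(dr, dc)
        # Shrink the shift deterministically until the candidate fits the body
        # and stays clear of the regions already placed and of the untouched
        # originals still to come. The zero shift always satisfies both (each
        # placed region was validated against this region's original), so the
        # loop terminates.
        rest = truth.regions[i + 1:]
        while True:
            try:
                dataclasses.replace(truth, regions=regions + [cand] + rest)
                break
            except GeometryError:
                dr = int(dr - np.sign(dr))
                dc = int(dc - np.sign(dc))
                cand = r.shifted(dr, dc)
        regions.append(cand)
    out = dataclasses.replace(truth, regions=regions)
    out.validate_geometry()
    return out


def generate_cohort(
    truth: PhantomTruth,
    n_subjects: int,
    timepoints: Sequence[float],
    seed: int | None = None,
    variation: CohortVariation | None = None,
) -> list[tuple[NIRImage, RegionSet]]:
    """Cohort of ``n_subjects`` animals imaged at each timepoint.

    Sub-seeds derive deterministically from ``seed`` via ``SeedSequence(seed)``
    spawning one child per subject and one grandchild per frame; frames are
    returned ordered by subject then timepoint. With ``variation`` disabled
    (both fields 0) each frame equals ``generate_phantom`` run with the derived
    frame seed.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if len(timepoints) == 0:
        raise ValidationError("timepoints must be non-empty")
    if seed is None:
        seed = truth.seed
    variation = variation if variation is not None else CohortVariation()

    frames: list[tuple[NIRImage, RegionSet]] = []
    subject_seqs = np.random.SeedSequence(seed).spawn(n_subjects)
    for s_idx, sseq in enumerate(subject_seqs):
        srng = np.random.default_rng(sseq)
        subj_truth = _jitter_regions(truth, srng, variation.center_jitter_px)
        regions = []
        for r in subj_truth.regions:
            sig = variation.amplitude_sigma(r.name)
            if sig > 0 and r.c_max > 0:
                # mean-one lognormal so the cohort-average uptake is unbiased
                scale = float(np.exp(srng.normal(-0.5 * sig**2, sig)))
                r = dataclasses.replace(r, c_max=r.c_max * scale)
            regions.append(r)
        subj_truth = dataclasses.replace(subj_truth, regions=regions)
        subject_id = f"m{s_idx + 1}"
        frame_seqs = sseq.spawn(len(timepoints))
        for t, fseq in zip(timepoints, frame_seqs):
            frame_seed = int(fseq.generate_state(1)[0] % (2**31))
            L = truth.luminosity
            if variation.luminosity_sigma_log > 0:
                L = L * float(np.exp(srng.normal(0.0, variation.luminosity_sigma_log)))
            frame_truth = dataclasses.replace(
                subj_truth, luminosity=L, seed=frame_seed
            )
            frames.append(generate_phantom(frame_truth, t, subject_id=subject_id))
    return frames


# ---------------------------------------------------------------------------
# ex vivo lungs
# ---------------------------------------------------------------------------

@dataclass
class LungPhantomTruth:
    """Generative parameters for an excised-lung phantom with melanoma nodes.

    ``diffuse_level`` is the uniform lung signal in the diffuse stage (the ex
    vivo dose is 1/10 of the in vivo one, hence the low default). In the
    localized stage the diffuse component drops to ``localized_diffuse_factor``
    of that and each node gains a rim of width ``rim_width`` at
    ``rim_amplitude`` above the residual diffuse level; node cores gain only
    ``node_core_level`` (the agent decorates the periphery of a cluster, not
    its interior).
    """

    image_shape: tuple[int, int] = (96, 96)
    lobe_centers: tuple[tuple[float, float], ...] = ((48.0, 33.0), (48.0, 63.0))
    lobe_radii: tuple[tuple[float, float], ...] = ((30.0, 15.0), (30.0, 15.0))
    node_count: int = 8
    node_radius: int = 3
    node_positions: list[tuple[int, int]] | Literal["random"] = "random"
    diffuse_level: float = 8.0
    rim_amplitude: float = 20.0
    rim_width: int = 2
    node_core_level: float = 2.0
    localized_diffuse_factor: float = 0.3
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.node_count < 0:
            raise ValidationError("node_count must be >= 0")
        if self.rim_width < 1:
            raise ValidationError("rim_width must be >= 1")
        if min(self.diffuse_level, self.rim_amplitude, self.node_core_level) < 0:
            raise ValidationError("intensity levels must be >= 0")

    def lung_mask(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        for c, r in zip(self.lobe_centers, self.lobe_radii):
            m |= _ellipse_mask(self.image_shape, c, r)
        return m

    def with_noise_off(self) -> "LungPhantomTruth":
        return dataclasses.replace(self, noise=NoiseModel.off())


def _chebyshev_ring(center: tuple[int, int], inner: int, outer: int,
                    shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.maximum(np.abs(rr - center[0]), np.abs(cc - center[1]))
    return (d > inner) & (d <= outer)


def _node_disc(center, radius, shape) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.maximum(np.abs(rr - center[0]), np.abs(cc - center[1]))
    return d <= radius


def _place_nodes(truth: LungPhantomTruth,
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    margin = truth.node_radius + truth.rim_width
    lung = truth.lung_mask()
    if truth.node_positions != "random":
        positions = [tuple(int(v) for v in p) for p in truth.node_positions]
        for p in positions:
            footprint = _node_disc(p, margin, truth.image_shape)
            if np.any(footprint & ~lung):
                raise GeometryError(f"node at {p} (plus rim) leaves the lung mask")
        return positions
    # Rejection-sample centers whose node+rim footprint stays inside the lung
    # and does not touch any previously placed footprint.
    from scipy.ndimage import distance_transform_cdt

    interior = distance_transform_cdt(lung, metric="chessboard") > margin
    rows, cols = np.nonzero(interior)
    if truth.node_count > 0 and rows.size == 0:
        raise GeometryError("no feasible node placement inside the lung mask")
    positions: list[tuple[int, int]] = []
    min_sep = 2 * margin + 1
    for _ in range(10_000):
        if len(positions) == truth.node_count:
            break
        i = int(rng.integers(rows.size))
        cand = (int(rows[i]), int(cols[i]))
        if all(max(abs(cand[0] - p[0]), abs(cand[1] - p[1])) >= min_sep
               for p in positions):
            positions.append(cand)
    if len(positions) < truth.node_count:
        raise GeometryError(
            f"could only place {len(positions)}/{truth.node_count} nodes"
        )
    return positions


def generate_lung_exvivo(
    truth: LungPhantomTruth,
    stage: Literal["diffuse", "localized"],
) -> tuple[NIRImage, RegionSet]:
    """Excised-lung frame at the diffuse (1 h) or localized (24 h) stage.

    Diffuse: uniform ``diffuse_level`` over the lung; nodes exist in the
    RegionSet but are not enhanced. Localized: residual diffuse level plus
    bright rims around each node. Same truth + seed gives identical node
    placement and noise in both stages.
    """
    if stage not in ("diffuse", "localized"):
        raise ValidationError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(truth.seed)
    lung = truth.lung_mask()
    positions = _place_nodes(truth, rng) if truth.node_count > 0 else []

    shape = truth.image_shape
    clean = np.zeros(shape, dtype=np.float64)
    if stage == "diffuse":
        clean[lung] = truth.diffuse_level
    else:
        clean[lung] = truth.diffuse_level * truth.localized_diffuse_factor
        for p in positions:
            rim = _chebyshev_ring(p, truth.node_radius,
                                  truth.node_radius + truth.rim_width, shape)
            clean[rim] += truth.rim_amplitude
            clean[_node_disc(p, truth.node_radius, shape)] += truth.node_core_level

    px = _apply_noise(clean, truth.noise, rng)
    img = NIRImage(px, meta=ImageMeta(subject_id="lungs", timepoint_h=None,
                                      view="ex_vivo"))

    lm = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    lab = 1
    for k, p in enumerate(positions, start=1):
        lm[_node_disc(p, truth.node_radius, shape)] = lab
        names[lab] = f"node_{k}"
        lab += 1
        lm[_chebyshev_ring(p, truth.node_radius,
                           truth.node_radius + truth.rim_width, shape)] = lab
        names[lab] = f"rim_{k}"
        lab += 1
    regions = RegionSet(lm, names, aux_masks={"lung": lung, "body": lung})
    return img, regions
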