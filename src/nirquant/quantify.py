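"""Normalized signal-to-noise quantification for planar NIR images.

The per-ROI statistic is built in four steps:

1. **Hip normalization** — every image is rescaled so the mean over a hip
   reference ROI hits a fixed level R (default 100 arbitrary units). This
   removes per-image global luminosity differences between animals and
   timepoints; every downstream statistic is invariant to a global rescaling
   of the input by construction.
2. **Autofluorescence** A — the intrinsic tissue signal, estimated from a
   pre-injection / uninjected control image (mean over the body after hip
   normalization), or, as a fallback, taken as the hip level itself (the hip
   carries no agent, so its normalized level R is the autofluorescence scale).
3. **Background** — mean and SD over a scattered-light annulus near the ROI.
4. **SNR** — ``noise_sd`` mode (default): (ROI mean − A) / SD(background);
   ``mean_ratio`` mode: (ROI mean − A) / (background mean − A). Signed values
   are reported as-is: an ROI dimmer than the autofluorescence scores
   negative, and clipping would bias cohort means.

Pixel statistics use the population SD; cohort summaries (mean ± SD over N
animals) use the sample SD.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion

from .errors import (
    ConfigurationError,
    DegenerateBackgroundError,
    EmptyRegionError,
    NormalizationError,
    ShapeMismatchError,
    ValidationError,
)
from .imaging_io import NIRImage, RegionSet
from .roi_detection import background_annulus, hip_reference_roi

__all__ = [
    "ROIStats",
    "TimeCourseTable",
    "QuantConfig",
    "mean_intensity",
    "hip_normalize",
    "estimate_autofluorescence",
    "snr",
    "biodistribution",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class ROIStats:
    """Full quantification record for one (subject, ROI, timepoint)."""

    subject_id: str
    timepoint_h: float
    roi_name: str
    n_pixels: int
    raw_mean: float
    raw_sd: float
    norm_factor: float      # hip normalization factor f
    autofluorescence: float  # A, in normalized units
    bg_mean: float
    bg_sd: float
    snr: float
    snr_mode: str

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValidationError("n_pixels must be >= 1")
        if not self.norm_factor > 0:
            raise ValidationError("norm_factor must be > 0")
        if self.bg_sd < 0:
            raise ValidationError("bg_sd must be >= 0")
        if not np.isfinite(self.snr):
            raise ValidationError("snr must be finite")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TimeCourseTable:
    """Per-measurement rows plus cohort mean ± SD summary."""

    measurements: pd.DataFrame  # subject_id, roi_name, timepoint_h, snr
    summary: pd.DataFrame       # roi_name, timepoint_h, mean_snr, sd_snr, n
    roi_stats: list[ROIStats] = field(default_factory=list)

    def summary_value(self, roi_name: str, timepoint_h: float,
                      column: str = "mean_snr") -> float:
        s = self.summary
        row = s[(s.roi_name == roi_name) & (s.timepoint_h == timepoint_h)]
        if row.empty:
            raise KeyError((roi_name, timepoint_h))
        return float(row.iloc[0][column])


@dataclass
class QuantConfig:
    """Configuration of the quantification pipeline."""

    reference_level: float = 100.0  # R: hip level after normalization
    snr_mode: str = "noise_sd"      # noise_sd | mean_ratio
    annulus_r_in: int = 3
    annulus_r_out: int = 10
    body_edge_margin: int = 8
    rois: Sequence[str] | None = None  # default: every named ROI except hip_ref
    autofluorescence_source: str = "hip"  # hip | control
    # Fraction of the hip signal that is autofluorescence, for the hip
    # fallback: A = R * fraction. 1.0 means the hip takes up no agent.
    hip_autofluorescence_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_level <= 0:
            raise ValidationError("reference_level must be > 0")
        if self.snr_mode not in ("noise_sd", "mean_ratio"):
            raise ValidationError(f"unknown snr_mode {self.snr_mode!r}")
        if self.autofluorescence_source not in ("hip", "control"):
            raise ValidationError("autofluorescence_source must be hip|control")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def mean_intensity(image: NIRImage, mask: np.ndarray) -> tuple[float, float, int]:
    """Arithmetic mean, population SD and pixel count over a mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ShapeMismatchError(f"mask {mask.shape} vs image {image.shape}")
    vals = image.pixels[mask]
    if vals.size == 0:
        raise EmptyRegionError("mean_intensity over an empty mask")
    mean = float(np.mean(vals))
    sd = float(np.sqrt(np.mean((vals - mean) ** 2)))
    return mean, sd, int(vals.size)


def hip_normalize(
    image: NIRImage,
    hip_mask: np.ndarray,
    reference_level: float = 100.0,
) -> tuple[NIRImage, float]:
    """Rescale so the hip-ROI mean equals ``reference_level``.

    Returns the normalized image and the factor f = R / mean(hip).
    """
    if reference_level <= 0:
        raise ValidationError("reference_level must be > 0")
    hip_mean, _, _ = mean_intensity(image, hip_mask)
    if hip_mean <= 0:
        raise NormalizationError("hip-ROI mean is zero; cannot normalize")
    f = reference_level / hip_mean
    return image.scaled(f), f


def estimate_autofluorescence(
    control: NIRImage,
    body_mask: np.ndarray,
    hip_mask: np.ndarray | None = None,
    reference_level: float = 100.0,
    edge_margin: int = 0,
) -> float:
    """Autofluorescence A from a pre-injection or uninjected control image.

    In vivo: the control is hip-normalized and A is its mean over the body
    mask. Ex vivo (``hip_mask=None``): A is the plain mean over the mask (the
    lungs), with no normalization. ``edge_margin`` optionally erodes the mask
    to exclude the blur-contaminated rim at the body outline.
    """
    mask = np.asarray(body_mask, dtype=bool)
    if edge_margin > 0:
        size = 2 * edge_margin + 1
        mask = binary_erosion(mask, structure=np.ones((size, size), dtype=bool))
        if not mask.any():
            raise EmptyRegionError("body mask empty after edge erosion")
    if hip_mask is None:
        a, _, _ = mean_intensity(control, mask)
        return a
    normed, _ = hip_normalize(control, hip_mask, reference_level)
    a, _, _ = mean_intensity(normed, mask)
    return a


def snr(
    image_norm: NIRImage,
    roi_mask: np.ndarray,
    bg_mask: np.ndarray,
    autofluorescence: float,
    mode: str = "noise_sd",
    reference_level: float = 100.0,
) -> float:
    """Normalized signal-to-noise of one ROI on a hip-normalized image.

    ``noise_sd``: (mean_ROI − A) / SD(background);
    ``mean_ratio``: (mean_ROI − A) / max(mean_background − A, 1e-9·R).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if np.any(roi_mask & bg_mask):
        raise ValidationError("ROI and background masks overlap")
    m_roi, _, _ = mean_intensity(image_norm, roi_mask)
    m_bg, sd_bg, _ = mean_intensity(image_norm, bg_mask)
    num = m_roi - autofluorescence
    if mode == "noise_sd":
        if sd_bg == 0:
            raise DegenerateBackgroundError(
                "background annulus has zero SD; widen the annulus"
            )
        return num / sd_bg
    if mode == "mean_ratio":
        eps = 1e-9 * reference_level
        return num / max(m_bg - autofluorescence, eps)
    raise ValidationError(f"unknown snr mode {mode!r}")


# ---------------------------------------------------------------------------
# the full time course
# ---------------------------------------------------------------------------

def _frame_key(image: NIRImage) -> tuple[str, float]:
    sid = image.meta.subject_id or "subject"
    t = image.meta.timepoint_h
    if t is None:
        raise ConfigurationError("frame is missing timepoint_h metadata")
    return sid, float(t)


def quantify_frame(
    image: NIRImage,
    regions: RegionSet,
    config: QuantConfig | None = None,
    control: NIRImage | None = None,
) -> list[ROIStats]:
    """Quantify every requested ROI on one frame. See :func:`biodistribution`."""
    config = config or QuantConfig()
    regions.validate_against(image)
    sid, t = _frame_key(image)

    hip = hip_reference_roi(regions)
    normed, f = hip_normalize(image, hip, config.reference_level)

    if config.autofluorescence_source == "control" or control is not None:
        if control is None:
            raise ConfigurationError(
                "autofluorescence_source='control' but no control image given; "
                "use autofluorescence_source='hip' for the hip fallback"
            )
        a = estimate_autofluorescence(
            control, regions.body_mask, hip, config.reference_level
        )
    else:
        a = config.reference_level * config.hip_autofluorescence_fraction

    roi_names = list(config.rois) if config.rois is not None else [
        n for n in regions.region_names if n != "hip_ref"
    ]
    out: list[ROIStats] = []
    for name in roi_names:
        roi = regions.mask(name)
        bg = background_annulus(
            regions, name, config.annulus_r_in, config.annulus_r_out,
            config.body_edge_margin,
        )
        raw_mean, raw_sd, n_px = mean_intensity(image, roi)
        bg_mean, bg_sd, _ = mean_intensity(normed, bg)
        value = snr(normed, roi, bg, a, config.snr_mode, config.reference_level)
        out.append(ROIStats(
            subject_id=sid, timepoint_h=t, roi_name=name, n_pixels=n_px,
            raw_mean=raw_mean, raw_sd=raw_sd, norm_factor=f,
            autofluorescence=a, bg_mean=bg_mean, bg_sd=bg_sd,
            snr=value, snr_mode=config.snr_mode,
        ))
    return out


def biodistribution(
    frames: Iterable[tuple],
    config: QuantConfig | None = None,
) -> TimeCourseTable:
    """Assemble the full (subject × ROI × timepoint) SNR time course.

    ``frames`` yields ``(image, regions)`` or ``(image, regions, control)``
    tuples; subject and timepoint come from the image metadata. A frame/ROI
    whose quantification fails is logged and dropped from the table rather
    than aborting the run. Summary rows carry the cohort mean, sample SD and
    contributing subject count per (ROI, timepoint).
    """
    config = config or QuantConfig()
    stats: list[ROIStats] = []
    for frame in frames:
        image, regions = frame[0], frame[1]
        control = frame[2] if len(frame) > 2 else None
        try:
            stats.extend(quantify_frame(image, regions, config, control))
        except Exception as exc:  # noqa: BLE001 - per-row exclusion is the contract
            sid = image.meta.subject_id
            log.warning("frame %s @ %sh dropped: %s", sid,
                        image.meta.timepoint_h, exc)

    cols = ["subject_id", "roi_name", "timepoint_h", "snr"]
    if not stats:
        empty = pd.DataFrame(columns=cols)
        summary = pd.DataFrame(
            columns=["roi_name", "timepoint_h", "mean_snr", "sd_snr", "n"]
        )
        return TimeCourseTable(empty, summary, [])

    measurements = pd.DataFrame([{c: getattr(s, c) for c in cols} for s in stats])
    measurements = measurements.sort_values(cols[:3]).reset_index(drop=True)
    grouped = measurements.groupby(["roi_name", "timepoint_h"])["snr"]
    summary = grouped.agg(
        mean_snr="mean",
        sd_snr=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        n="count",
    ).reset_index().sort_values(["roi_name", "timepoint_h"]).reset_index(drop=True)
    return TimeCourseTable(measurements, summary, stats)
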