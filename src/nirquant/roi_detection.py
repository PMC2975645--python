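"""Threshold-based ROI determination and background-annulus construction.

ROIs are found by thresholding a fluorescence image — optionally against a
second, skin-removed reference frame — and keeping connected components above
a minimum area. When a reference is given the working image is the pixelwise
minimum of the two: a candidate ROI pixel must be bright in both frames, which
suppresses skin-scatter artifacts present in only one of them. The "scattered
light" background for a given ROI is sampled from a ring (annulus) around it,
restricted to the interior of the body and excluding every other named ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_cdt
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import (
    AnnulusError,
    ConfigurationError,
    DetectionError,
    EmptyRegionError,
    ShapeMismatchError,
    ValidationError,
)
from .imaging_io import NIRImage, RegionSet

__all__ = [
    "ThresholdParams",
    "detect_rois",
    "background_annulus",
    "hip_reference_roi",
]


@dataclass
class ThresholdParams:
    """Parameters for threshold ROI detection.

    ``min_area`` (default 25 px) rejects small bright specks such as
    incompletely removed hairs. ``seed_points`` maps a region name to a
    (row, col) pixel; the detected component containing that pixel becomes the
    region. ``restrict_to`` limits thresholding and detection to a mask
    (normally the body).
    """

    method: str = "otsu"  # otsu | quantile
    quantile_q: float = 0.95
    min_area: int = 25
    seed_points: dict[str, tuple[int, int]] | None = None
    restrict_to: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "quantile"):
            raise ValidationError(f"unknown threshold method {self.method!r}")
        if not 0.0 < self.quantile_q < 1.0:
            raise ValidationError("quantile_q must be in (0, 1)")
        if self.min_area < 1:
            raise ValidationError("min_area must be >= 1")


def detect_rois(
    image: NIRImage,
    reference: NIRImage | None,
    params: ThresholdParams | None = None,
) -> RegionSet:
    """Threshold analysis of ``image`` (against ``reference`` if given).

    Pixels strictly above the threshold are grouped into 8-connected
    components; components smaller than ``min_area`` are dropped. With seed
    points, each named region is the component containing its seed (a missing
    component is a :class:`DetectionError`); otherwise surviving components are
    named ``roi_1..roi_n`` in order of decreasing mean intensity. A constant
    image yields an empty RegionSet (with a warning), never a whole-image ROI:
    pixels exactly at the threshold are excluded.
    """
    params = params or ThresholdParams()
    working = image.pixels
    if reference is not None:
        if reference.shape != image.shape:
            raise ShapeMismatchError(
                f"reference {reference.shape} vs image {image.shape}"
            )
        working = np.minimum(working, reference.pixels)

    if params.restrict_to is not None:
        restrict = np.asarray(params.restrict_to, dtype=bool)
        if restrict.shape != image.shape:
            raise ShapeMismatchError("restrict_to mask shape mismatch")
    else:
        restrict = np.ones(image.shape, dtype=bool)

    vals = working[restrict]
    if vals.size == 0:
        raise EmptyRegionError("restrict_to mask is empty")
    if params.method == "otsu":
        if vals.min() == vals.max():
            thr = float(vals[0])
        else:
            thr = float(threshold_otsu(vals))
    else:
        thr = float(np.quantile(vals, params.quantile_q))

    binary = (working > thr) & restrict
    labels = cc_label(binary, connectivity=2)
    keep: list[int] = []
    for lab in range(1, labels.max() + 1):
        if np.count_nonzero(labels == lab) >= params.min_area:
            keep.append(lab)

    aux = {"body": restrict} if params.restrict_to is not None else {}
    if not keep:
        warnings.warn("threshold analysis found no ROI", stacklevel=2)
        return RegionSet(np.zeros(image.shape, dtype=np.int32), {}, aux_masks=aux)

    out = np.zeros(image.shape, dtype=np.int32)
    names: dict[int, str] = {}
    if params.seed_points:
        for i, (name, (r, c)) in enumerate(sorted(params.seed_points.items()),
                                           start=1):
            lab = int(labels[int(r), int(c)])
            if lab == 0 or lab not in keep:
                raise DetectionError(
                    f"seed point for region {name!r} lies in no detected component"
                )
            out[labels == lab] = i
            names[i] = name
    else:
        means = {lab: float(working[labels == lab].mean()) for lab in keep}
        ranked = sorted(keep, key=lambda lab: (-means[lab], lab))
        for i, lab in enumerate(ranked, start=1):
            out[labels == lab] = i
            names[i] = f"roi_{i}"
    return RegionSet(out, names, aux_masks=aux)


def background_annulus(
    regions: RegionSet,
    roi_name: str,
    r_in: int = 3,
    r_out: int = 10,
    body_edge_margin: int = 8,
) -> np.ndarray:
    """Scattered-light sampling ring around a named ROI.

    Pixels at Chebyshev distance in (``r_in``, ``r_out``] from the ROI,
    intersected with the body interior and with every other named ROI removed.
    The body is first eroded by ``body_edge_margin`` pixels so the ring samples
    scattered light from internal organs rather than the intensity falloff at
    the skin/body outline. The ring never intersects its own ROI.
    """
    if not (0 <= r_in < r_out):
        raise ValidationError("need 0 <= r_in < r_out")
    roi = regions.mask(roi_name)
    if not roi.any():
        raise EmptyRegionError(f"ROI {roi_name!r} is empty")
    dist = distance_transform_cdt(~roi, metric="chessboard")
    ring = (dist > r_in) & (dist <= r_out)

    if "body" in regions.aux_masks:
        body = regions.aux_masks["body"]
        if body_edge_margin > 0:
            size = 2 * body_edge_margin + 1
            body = binary_erosion(body, structure=np.ones((size, size), dtype=bool))
    else:  # open field: no body outline known
        body = np.ones(roi.shape, dtype=bool)
    others = (regions.label_map > 0) & ~roi
    annulus = ring & body & ~others
    if not annulus.any():
        raise AnnulusError(
            f"background annulus for {roi_name!r} is empty; increase r_out"
        )
    return annulus


def hip_reference_roi(regions: RegionSet) -> np.ndarray:
    """The hip-reference mask used for global luminosity normalization."""
    if not regions.has("hip_ref"):
        raise ConfigurationError(
            "RegionSet has no 'hip_ref' region; hip normalization cannot proceed"
        )
    hip = regions.mask("hip_ref")
    if not hip.any():
        raise EmptyRegionError("hip_ref region is empty")
    try:
        lab = regions.label_of("hip_ref")
        others = (regions.label_map > 0) & (regions.label_map != lab)
    except KeyError:  # hip_ref stored as an aux mask
        others = regions.label_map > 0
    if np.any(hip & others):
        raise ValidationError("hip_ref overlaps another named ROI")
    return hip
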