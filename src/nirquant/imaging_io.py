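"""Image, region-set and overlay I/O for planar NIR fluorescence imaging.

Images are single-plane grayscale TIFFs (8/16-bit integer or 32-bit float)
holding linear intensity in arbitrary units. Acquisition metadata travels in a
JSON sidecar next to the TIFF rather than in TIFF tags, so files stay portable
across readers. Named pixel regions (tumor, organs, hip reference, ...) are a
single integer label map plus a JSON label->name map; regions that may overlap
the labeled ones (the whole-body mask, background annuli) are carried as
auxiliary boolean masks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
from matplotlib import colormaps

from .errors import (
    ShapeMismatchError,
    UnsupportedFormatError,
    ValidationError,
)

__all__ = [
    "ImageMeta",
    "NIRImage",
    "RegionSet",
    "read_image",
    "write_image",
    "read_regions",
    "write_regions",
    "composite_overlay",
]

MIN_SHAPE = 16

#: Kodak Image Station NIR filter set used throughout: 710 nm ex / 790 nm em.
DEFAULT_EXCITATION_NM = 710.0
DEFAULT_EMISSION_NM = 790.0


@dataclass
class ImageMeta:
    """Acquisition metadata for one planar frame."""

    subject_id: str | None = None
    timepoint_h: float | None = None
    view: str = "unknown"  # side | dorsal | ex_vivo | unknown
    excitation_nm: float = DEFAULT_EXCITATION_NM
    emission_nm: float = DEFAULT_EMISSION_NM

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImageMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class NIRImage:
    """One planar fluorescence frame: non-negative linear intensities + metadata."""

    pixels: np.ndarray
    pixel_size_mm: float | None = None
    meta: ImageMeta = field(default_factory=ImageMeta)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"image must be 2-D, got ndim={px.ndim}")
        if px.shape[0] < MIN_SHAPE or px.shape[1] < MIN_SHAPE:
            raise ValidationError(
                f"image must be at least {MIN_SHAPE}x{MIN_SHAPE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite pixel values")
        if np.any(px < 0):
            raise ValidationError("image contains negative intensities")
        if self.meta.timepoint_h is not None and self.meta.timepoint_h < 0:
            raise ValidationError("timepoint_h must be >= 0")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def scaled(self, factor: float) -> "NIRImage":
        """Return a copy with every pixel multiplied by ``factor`` (>0)."""
        if factor <= 0:
            raise ValidationError("scale factor must be > 0")
        return NIRImage(self.pixels * factor, self.pixel_size_mm,
                        dataclasses.replace(self.meta))


@dataclass
class RegionSet:
    """Named pixel regions aligned to one image.

    ``label_map`` assigns each pixel at most one named ROI (0 = unassigned), so
    named ROIs are disjoint by construction. Regions that legitimately overlap
    them — the body outline, derived background annuli — live in ``aux_masks``.
    """

    label_map: np.ndarray
    names: dict[int, str]
    aux_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lm = np.asarray(self.label_map)
        if lm.ndim != 2:
            raise ValidationError("label map must be 2-D")
        if not np.issubdtype(lm.dtype, np.integer):
            raise ValidationError("label map must be integer-typed")
        self.label_map = lm.astype(np.int32)
        self.names = {int(k): str(v) for k, v in self.names.items()}
        if 0 in self.names:
            raise ValidationError("label 0 is reserved for unassigned pixels")
        present = set(np.unique(self.label_map).tolist()) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValidationError(
                f"name map references absent labels: {sorted(missing)}"
            )
        self.aux_masks = {
            k: np.asarray(v, dtype=bool) for k, v in self.aux_masks.items()
        }
        for k, m in self.aux_masks.items():
            if m.shape != self.label_map.shape:
                raise ShapeMismatchError(f"aux mask {k!r} shape mismatch")

    # -- lookups ---------------------------------------------------------
    @property
    def region_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]

    def has(self, name: str) -> bool:
        return name in self.names.values() or name in self.aux_masks

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(name)

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of a named ROI or auxiliary region."""
        for lab, nm in self.names.items():
            if nm == name:
                return self.label_map == lab
        if name in self.aux_masks:
            return self.aux_masks[name].copy()
        raise KeyError(f"no region named {name!r}")

    @property
    def body_mask(self) -> np.ndarray:
        """Body outline: the 'body' aux mask if present, else the union of ROIs."""
        if "body" in self.aux_masks:
            return self.aux_masks["body"].copy()
        return self.label_map > 0

    def validate_against(self, image: NIRImage) -> None:
        if self.label_map.shape != image.shape:
            raise ShapeMismatchError(
                f"regions {self.label_map.shape} vs image {image.shape}"
            )
        if "body" in self.aux_masks:
            body = self.aux_masks["body"]
            outside = (self.label_map > 0) & ~body
            if np.any(outside):
                bad = sorted(
                    {self.names.get(int(v), str(v))
                     for v in np.unique(self.label_map[outside]) if v != 0}
                )
                raise ValidationError(f"ROIs extend outside the body: {bad}")


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(img: NIRImage, path: str | Path, dtype: str = "auto") -> Path:
    """Write a TIFF plus a JSON metadata sidecar.

    ``dtype='auto'`` stores integral data fitting 16 bits as uint16, anything
    else as 32-bit float. Round trips are exact for uint16 data and for floats
    representable in float32.
    """
    path = Path(path)
    px = img.pixels
    if dtype == "auto":
        integral = np.all(px == np.round(px)) and px.max(initial=0.0) <= 65535
        dtype = "uint16" if integral else "float32"
    if dtype == "uint16":
        data = np.clip(np.round(px), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = px.astype(np.float32)
    else:
        raise ValidationError(f"unsupported write dtype {dtype!r}")
    tifffile.imwrite(path, data)
    side = {"pixel_size_mm": img.pixel_size_mm, "meta": img.meta.to_dict()}
    _sidecar(path).write_text(json.dumps(side, sort_keys=True, indent=1))
    return path


def read_image(path: str | Path) -> NIRImage:
    """Read a single-plane grayscale TIFF (+ optional JSON sidecar)."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path.name}: expected a single grayscale plane, got shape {arr.shape}"
        )
    meta = ImageMeta()
    pixel_size = None
    sc = _sidecar(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        meta = ImageMeta.from_dict(side.get("meta", {}))
        pixel_size = side.get("pixel_size_mm")
    return NIRImage(arr, pixel_size, meta)


# ---------------------------------------------------------------------------
# region I/O
# ---------------------------------------------------------------------------

def write_regions(regions: RegionSet, path_mask: str | Path,
                  path_names: str | Path) -> None:
    """Write the label map as 16-bit TIFF, names + aux list as JSON.

    Aux masks are written next to the label TIFF as ``<stem>.aux_<name>.tif``
    (8-bit, 0/1).
    """
    path_mask = Path(path_mask)
    tifffile.imwrite(path_mask, regions.label_map.astype(np.uint16))
    aux_names = sorted(regions.aux_masks)
    doc = {"names": {str(k): v for k, v in regions.names.items()},
           "aux": aux_names}
    Path(path_names).write_text(json.dumps(doc, sort_keys=True, indent=1))
    for name in aux_names:
        p = path_mask.with_name(f"{path_mask.stem}.aux_{name}.tif")
        tifffile.imwrite(p, regions.aux_masks[name].astype(np.uint8))


def read_regions(path_mask: str | Path, path_names: str | Path) -> RegionSet:
    path_mask = Path(path_mask)
    lm = tifffile.imread(path_mask)
    if lm.ndim != 2:
        raise UnsupportedFormatError("label mask must be a single plane")
    doc = json.loads(Path(path_names).read_text())
    names = {int(k): v for k, v in doc.get("names", {}).items()}
    aux = {}
    for name in doc.get("aux", []):
        p = path_mask.with_name(f"{path_mask.stem}.aux_{name}.tif")
        aux[name] = tifffile.imread(p).astype(bool)
    return RegionSet(lm.astype(np.int32), names, aux)


# ---------------------------------------------------------------------------
# composite overlays
# ---------------------------------------------------------------------------

def composite_overlay(
    whitefield: NIRImage,
    nir: NIRImage,
    display_floor: float = 0.95,
    colormap: str = "hot",
    alpha: float = 0.6,
    body_mask: np.ndarray | None = None,
) -> np.ndarray:
    """White-field anatomical image with thresholded pseudocolor NIR on top.

    The floor is a quantile of the NIR intensities (within ``body_mask`` if
    given): pixels at or below it stay pure grayscale; pixels above it are
    pseudocolored and alpha-blended. Purely presentational — input arrays are
    never modified. Returns an (H, W, 3) uint8 RGB array.
    """
    if whitefield.shape != nir.shape:
        raise ShapeMismatchError(
            f"whitefield {whitefield.shape} vs nir {nir.shape}"
        )
    if not 0.0 <= display_floor < 1.0:
        raise ValidationError("display_floor must be in [0, 1)")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")

    wf = whitefield.pixels
    wmax = wf.max()
    gray = wf / wmax if wmax > 0 else np.zeros_like(wf)

    nirpx = nir.pixels
    pool = nirpx[body_mask] if body_mask is not None else nirpx.ravel()
    if pool.size == 0:
        raise ValidationError("empty body mask for overlay floor")
    floor_value = float(np.quantile(pool, display_floor))
    if display_floor == 0.0:
        colored = np.ones_like(nirpx, dtype=bool)
    else:
        colored = nirpx > floor_value

    cmap = colormaps[colormap]
    vmax = float(nirpx.max())
    span = vmax - floor_value
    norm = (nirpx - floor_value) / span if span > 0 else np.ones_like(nirpx)
    rgba = cmap(np.clip(norm, 0.0, 1.0))[..., :3]

    out = np.repeat(gray[..., None], 3, axis=2)
    out[colored] = (1.0 - alpha) * out[colored] + alpha * rgba[colored]
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
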