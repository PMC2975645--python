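"""Histogram analyses, ex vivo node localization, and report rendering.

Cumulative pixel histograms compare the intensity distribution inside a tumor
ROI against the rest of the body: a tumor that is both brighter (mean ratio
> 1) and narrower (SD ratio < 1) than the body separates cleanly in the
cumulative curves. For excised lungs bearing melanoma nodes, the localization
index scores whether fluorescence is diffuse over the lung (index near 1) or
concentrated in rims around the nodes (index >> 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import imageio.v3 as iio
import matplotlib.pyplot as plt
import numpy as np

from .errors import EmptyRegionError, ValidationError
from .imaging_io import NIRImage, RegionSet
from .quantify import TimeCourseTable, mean_intensity

__all__ = [
    "CumulativeHistogram",
    "LocalizationResult",
    "cumulative_histogram",
    "distribution_contrast",
    "node_localization",
    "render_report",
]


@dataclass
class CumulativeHistogram:
    """Cumulative frequency of masked pixel values, plus their mean and SD."""

    bin_edges: np.ndarray
    cum_freq: np.ndarray
    mask_name: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        cf = np.asarray(self.cum_freq, dtype=np.float64)
        if cf.size != edges.size - 1:
            raise ValidationError("len(cum_freq) must equal len(bin_edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(cf < -1e-12) or np.any(cf > 1 + 1e-12):
            raise ValidationError("cumulative frequencies must lie in [0, 1]")
        if np.any(np.diff(cf) < -1e-12):
            raise ValidationError("cumulative frequencies must be nondecreasing")
        self.bin_edges = edges
        self.cum_freq = cf


def cumulative_histogram(
    image: NIRImage,
    mask: np.ndarray,
    n_bins: int = 64,
    bin_edges: np.ndarray | None = None,
    mask_name: str = "",
) -> CumulativeHistogram:
    """Cumulative histogram of pixel values under ``mask``.

    Pass explicit ``bin_edges`` to compare two masks on a shared axis (the
    pooled min-max of both pixel sets is the usual choice).
    """
    mask = np.asarray(mask, dtype=bool)
    mean, sd, n = mean_intensity(image, mask)  # validates mask / emptiness
    vals = image.pixels[mask]
    if bin_edges is None:
        bin_edges = np.histogram_bin_edges(vals, bins=n_bins)
    counts, edges = np.histogram(vals, bins=bin_edges)
    cum = np.cumsum(counts) / n
    return CumulativeHistogram(edges, cum, mask_name, mean, sd)


def distribution_contrast(
    tumor_hist: CumulativeHistogram,
    body_hist: CumulativeHistogram,
) -> dict:
    """Tumor-vs-body contrast: mean ratio, SD ratio and a separability flag.

    ``separable`` is True when the tumor is brighter on average (mean ratio
    > 1) and its pixel distribution narrower (SD ratio < 1) than the body's.
    Requires histograms computed on shared bin edges.
    """
    if not np.array_equal(tumor_hist.bin_edges, body_hist.bin_edges):
        raise ValidationError("histograms must share bin edges")
    if body_hist.mean == 0:
        raise ValidationError("body mean is zero; contrast undefined")
    if body_hist.sd == 0:
        raise ValidationError("body SD is zero; contrast undefined")
    mean_ratio = tumor_hist.mean / body_hist.mean
    sd_ratio = tumor_hist.sd / body_hist.sd
    return {
        "mean_ratio": mean_ratio,
        "sd_ratio": sd_ratio,
        "separable": bool(mean_ratio > 1.0 and sd_ratio < 1.0),
    }


@dataclass
class LocalizationResult:
    """Ex vivo lung localization: rim-to-parenchyma index and lung CV."""

    stage: str
    localization_index: float | None
    lung_cv: float
    per_node_rim_means: dict[str, float] = field(default_factory=dict)
    no_nodes: bool = False


def node_localization(
    lung_image: NIRImage,
    regions: RegionSet,
    ring_width: int = 2,
    autofluorescence: float = 0.0,
    stage: str = "",
) -> LocalizationResult:
    """Score how concentrated lung fluorescence is around melanoma nodes.

    ``localization_index`` = (mean over the union of node rims − A) /
    (mean over the remaining lung tissue − A), with A the intrinsic lung
    fluorescence (from uninjected controls; 0 if unknown). Near 1 means
    diffuse signal; much greater than 1 means node-localized signal.
    ``lung_cv`` = SD/mean over the whole lung. If the RegionSet carries no
    precomputed rim masks, rims of width ``ring_width`` are grown around each
    node (Chebyshev distance), clipped to the lung.
    """
    if ring_width < 1:
        raise ValidationError("ring_width must be >= 1")
    if not regions.has("lung"):
        raise ValidationError("RegionSet has no 'lung' mask")
    lung = regions.mask("lung")
    m_lung, sd_lung, _ = mean_intensity(lung_image, lung)
    if m_lung == 0:
        raise ValidationError("lung mean is zero")
    lung_cv = sd_lung / m_lung

    node_names = sorted(n for n in regions.region_names if n.startswith("node_"))
    if not node_names:
        return LocalizationResult(stage, None, lung_cv, {}, no_nodes=True)

    from scipy.ndimage import distance_transform_cdt

    rim_union = np.zeros(lung_image.shape, dtype=bool)
    per_node: dict[str, float] = {}
    for name in node_names:
        k = name.split("node_", 1)[1]
        rim_name = f"rim_{k}"
        if regions.has(rim_name):
            rim = regions.mask(rim_name)
        else:
            node = regions.mask(name)
            dist = distance_transform_cdt(~node, metric="chessboard")
            rim = (dist > 0) & (dist <= ring_width) & lung
        if not rim.any():
            raise EmptyRegionError(f"rim around {name!r} is empty")
        rim_union |= rim
        per_node[name] = mean_intensity(lung_image, rim)[0]

    parenchyma = lung & ~rim_union
    if not parenchyma.any():
        raise EmptyRegionError("no lung tissue left outside the rims")
    m_rim, _, _ = mean_intensity(lung_image, rim_union)
    m_par, _, _ = mean_intensity(lung_image, parenchyma)
    denom = m_par - autofluorescence
    if denom <= 0:
        raise ValidationError("parenchyma mean does not exceed autofluorescence")
    index = (m_rim - autofluorescence) / denom
    if index < 0:
        raise ValidationError("localization index must be >= 0")
    return LocalizationResult(stage, index, lung_cv, per_node)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def render_report(
    table: TimeCourseTable,
    histograms: list[CumulativeHistogram] | None = None,
    composites: dict[str, np.ndarray] | None = None,
    out_dir: str | Path = "report",
) -> list[Path]:
    """Write CSV tables, a JSON summary, SNR bar charts and histogram plots.

    File names are deterministic; identical inputs produce byte-identical CSV
    and JSON outputs. Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    meas_path = out / "measurements.csv"
    table.measurements.to_csv(meas_path, index=False, float_format=_FLOAT_FMT)
    written.append(meas_path)
    summ_path = out / "summary.csv"
    table.summary.to_csv(summ_path, index=False, float_format=_FLOAT_FMT)
    written.append(summ_path)

    summary_doc: dict = {"n_measurements": int(len(table.measurements))}
    if table.measurements.empty:
        summary_doc["status"] = "no data"
    else:
        summary_doc["status"] = "ok"
        summary_doc["summary"] = [
            {k: (round(float(v), 10) if isinstance(v, (int, float, np.floating))
                 and k in ("mean_snr", "sd_snr") else
                 (int(v) if k == "n" else v))
             for k, v in row.items()}
            for row in table.summary.to_dict("records")
        ]
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary_doc, sort_keys=True, indent=1))
    written.append(json_path)

    if not table.summary.empty:
        written.append(_snr_barchart(table, out / "snr_timecourse.png"))
    if histograms:
        written.append(_histogram_plot(histograms, out / "cumulative_histograms.png"))
    for name, rgb in (composites or {}).items():
        p = out / f"composite_{name}.png"
        iio.imwrite(p, rgb)
        written.append(p)
    return written


def _snr_barchart(table: TimeCourseTable, path: Path) -> Path:
    s = table.summary
    rois = sorted(s.roi_name.unique())
    times = sorted(s.timepoint_h.unique())
    fig, ax = plt.subplots(figsize=(1.2 * max(len(rois), 4) + 2, 4))
    width = 0.8 / max(len(times), 1)
    x = np.arange(len(rois))
    for j, t in enumerate(times):
        means, sds = [], []
        for roi in rois:
            row = s[(s.roi_name == roi) & (s.timepoint_h == t)]
            means.append(float(row.mean_snr.iloc[0]) if not row.empty else 0.0)
            sds.append(float(row.sd_snr.iloc[0]) if not row.empty else 0.0)
        ax.bar(x + j * width, means, width, yerr=sds, capsize=2, label=f"{t} h")
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(rois, rotation=30, ha="right")
    ax.set_ylabel("normalized SNR (mean ± SD)")
    ax.legend(title="timepoint")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _histogram_plot(histograms: list[CumulativeHistogram], path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for h in histograms:
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        ax.step(centers, h.cum_freq, where="mid",
                label=h.mask_name or "(unnamed)")
    ax.set_xlabel("pixel value")
    ax.set_ylabel("cumulative frequency")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
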