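"""Positive-cell detection and quantification inside annotated tumor regions.

Mirrors the digital-pathology workflow used for chromogenic slides: smooth
the nuclear signal (hematoxylin concentration, or the OD sum when the
counterstain is weak), threshold it, split touching nuclei by a
distance-transform watershed, filter implausible nucleus areas, expand each
nucleus radially (bounded by neighbors) into a cell, and measure per-stain
OD statistics in the nucleus / cell / cytoplasm compartments. A cell belongs
to a region iff its centroid lies in the analysis mask (tumor minus
stroma, necrosis, and artifacts). Marker positivity is a simple OD threshold
on a chosen compartment statistic; summaries report positive-cell density in
cells/mm^2 and percent of all detected cells.

All detection parameters are explicit configuration — there is no per-slide
tuning; defaults are documented on :class:`DetectionParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import circle_perimeter
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels, watershed

from .errors import InputError
from .io_formats import RGBImage, RegionAnnotationSet
from .stain_deconvolution import StainMatrix, deconvolve, od_sum, rgb_to_od

__all__ = [
    "DetectionParams",
    "CellTable",
    "MarkerSummary",
    "detect_cells",
    "classify_positive",
    "summarize_region",
    "render_markup",
]

COMPARTMENTS = ("nucleus", "cell", "cytoplasm")
STATS = ("mean", "max")
CHANNELS = ("hematoxylin", "chromogen")


@dataclass(frozen=True)
class DetectionParams:
    """Cell-detection configuration.

    detection_channel
        ``hematoxylin_od`` (default; avoids counting chromogen-only debris)
        or ``od_sum`` (rescues nuclei with weak counterstain).
    nucleus_threshold
        OD threshold on the smoothed detection signal (default 0.1).
    min/max_nucleus_area
        Plausible nucleus area band in um^2 (default 10-400).
    cell_expansion
        Radial nucleus-to-cell expansion in um (default 5), constrained by
        neighboring cells.
    smoothing_sigma
        Gaussian sigma in um (default 1.5).
    """

    detection_channel: str = "hematoxylin_od"
    nucleus_threshold: float = 0.1
    min_nucleus_area: float = 10.0
    max_nucleus_area: float = 400.0
    cell_expansion: float = 5.0
    smoothing_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.detection_channel not in {"hematoxylin_od", "od_sum"}:
            raise InputError("detection_channel must be 'hematoxylin_od' or 'od_sum'")
        if not (0 < self.min_nucleus_area < self.max_nucleus_area):
            raise InputError("need 0 < min_nucleus_area < max_nucleus_area")
        if self.nucleus_threshold <= 0:
            raise InputError("nucleus_threshold must be positive")
        if self.cell_expansion < 0 or self.smoothing_sigma < 0:
            raise InputError("expansion and smoothing must be non-negative")


@dataclass
class CellTable:
    """Per-cell measurements plus marker labels.

    ``df`` columns: ``id``, centroid ``x``/``y`` (px), ``nucleus_area_um2``,
    ``{compartment}_{channel}_{stat}`` OD statistics, and one
    ``label_<marker>`` column ('positive'/'negative') per classified marker.
    """

    df: pd.DataFrame
    mpp: float
    round_id: str | None = None
    markers: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def labels(self, marker: str) -> pd.Series:
        col = f"label_{marker}"
        if col not in self.df.columns:
            raise InputError(f"no labels for marker {marker!r}")
        return self.df.set_index("id")[col]

    def positive_count(self, marker: str) -> int:
        return int((self.labels(marker) == "positive").sum())

    def with_df(self, df: pd.DataFrame) -> "CellTable":
        return CellTable(df=df, mpp=self.mpp, round_id=self.round_id, markers=list(self.markers))


@dataclass(frozen=True)
class MarkerSummary:
    """Slide/region-level positivity summary for one marker."""

    marker: str
    n_total_cells: int
    n_positive: int
    density_positive: float  # cells / mm^2
    percent_positive: float | None  # None when no cells detected
    analysis_area_mm2: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_total_cells):
            raise InputError("positive count outside [0, n_total]")


_MEASURE_COLUMNS = [
    f"{comp}_{chan}_{stat}" for comp in COMPARTMENTS for chan in CHANNELS for stat in STATS
]


def _empty_cells_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["id", "x", "y", "nucleus_area_um2", *_MEASURE_COLUMNS]
    )


def detect_cells(
    img: RGBImage,
    sm: StainMatrix,
    params: DetectionParams = DetectionParams(),
    mask: RegionAnnotationSet | None = None,
) -> CellTable:
    """Detect cells on a deconvolved tile and measure compartment OD stats.

    ``mask`` defaults to a tumor annotation covering the whole tile. Cells
    whose centroid falls outside the analysis mask are discarded.
    """
    if mask is None:
        mask = RegionAnnotationSet.full_tile(img.shape, img.mpp)
    if mask.analysis_area_mm2() <= 0:
        raise InputError("analysis mask has zero area")

    mpp = img.mpp
    od = rgb_to_od(img)
    channels = deconvolve(od, sm)
    hema = np.clip(channels.conc[..., 0], 0.0, None)
    chrom = np.clip(channels.conc[..., 1], 0.0, None)
    signal = hema if params.detection_channel == "hematoxylin_od" else od_sum(od)

    sigma_px = params.smoothing_sigma / mpp
    smoothed = gaussian(signal, sigma=sigma_px, preserve_range=True) if sigma_px > 0 else signal
    binary = smoothed >= params.nucleus_threshold
    if not binary.any():
        return CellTable(df=_empty_cells_frame(), mpp=mpp, round_id=img.round_id)

    distance = ndi.distance_transform_edt(binary)
    min_sep_px = max(1, int(round(2.0 * math.sqrt(params.min_nucleus_area / math.pi) / mpp)))
    blobs = cc_label(binary)
    peaks = peak_local_max(
        distance, min_distance=min_sep_px, labels=blobs, exclude_border=False
    )
    seeds = np.zeros_like(blobs)
    for k, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = k
    nuclei = watershed(-distance, markers=seeds, mask=binary)

    # area filter in physical units
    px_area_um2 = mpp * mpp
    ids, counts = np.unique(nuclei[nuclei > 0], return_counts=True)
    keep = {
        i
        for i, cnt in zip(ids, counts)
        if params.min_nucleus_area <= cnt * px_area_um2 <= params.max_nucleus_area
    }
    nuclei = np.where(np.isin(nuclei, list(keep)), nuclei, 0)
    if not keep:
        return CellTable(df=_empty_cells_frame(), mpp=mpp, round_id=img.round_id)

    cells = expand_labels(nuclei, distance=params.cell_expansion / mpp)
    cyto = np.where(nuclei > 0, 0, cells)

    chan_maps = {"hematoxylin": hema, "chromogen": chrom}
    comp_maps = {"nucleus": nuclei, "cell": cells, "cytoplasm": cyto}
    rows = []
    for lab in sorted(keep):
        nuc_mask = nuclei == lab
        ys, xs = np.nonzero(nuc_mask)
        rec = {
            "id": int(lab),
            "x": float(xs.mean()),
            "y": float(ys.mean()),
            "nucleus_area_um2": float(nuc_mask.sum() * px_area_um2),
        }
        for comp, lab_map in comp_maps.items():
            sel = lab_map == lab
            for chan, cmap in chan_maps.items():
                vals = cmap[sel]
                rec[f"{comp}_{chan}_mean"] = float(vals.mean()) if vals.size else 0.0
                rec[f"{comp}_{chan}_max"] = float(vals.max()) if vals.size else 0.0
        rows.append(rec)
    df = pd.DataFrame(rows)

    inside = mask.contains_points(df["x"].to_numpy(), df["y"].to_numpy())
    df = df[inside].reset_index(drop=True)
    df["id"] = np.arange(1, len(df) + 1)
    return CellTable(df=df, mpp=mpp, round_id=img.round_id)


def classify_positive(
    cells: CellTable,
    marker: str,
    compartment: str = "nucleus",
    stat: str = "mean",
    threshold: float = 0.2,
) -> CellTable:
    """Label each cell positive iff its chromogen OD statistic >= threshold.

    Idempotent; labels are stored under ``label_<marker>`` and the result is
    a new table (the input is never mutated).
    """
    if compartment not in COMPARTMENTS:
        raise InputError(f"unknown compartment {compartment!r}")
    if stat not in STATS:
        raise InputError(f"unknown statistic {stat!r}")
    col = f"{compartment}_chromogen_{stat}"
    df = cells.df.copy()
    if len(df):
        df[f"label_{marker}"] = np.where(df[col] >= threshold, "positive", "negative")
    else:
        df[f"label_{marker}"] = pd.Series(dtype=str)
    out = cells.with_df(df)
    if marker not in out.markers:
        out.markers.append(marker)
    return out


def summarize_region(
    cells: CellTable, marker: str, mask: RegionAnnotationSet
) -> MarkerSummary:
    """Density (cells/mm^2) and percent positive within the analysis mask.

    Assumes ``cells`` was detected against the same mask; the area comes
    from the mask's polygon algebra at its stated mpp. With zero detected
    cells the percentage is explicitly undefined (None) and density is 0.
    """
    area = mask.analysis_area_mm2()
    if area <= 0:
        raise InputError("analysis mask has zero area")
    n_total = len(cells)
    if n_total == 0:
        return MarkerSummary(marker, 0, 0, 0.0, None, area)
    n_pos = cells.positive_count(marker)
    return MarkerSummary(
        marker=marker,
        n_total_cells=n_total,
        n_positive=n_pos,
        density_positive=n_pos / area,
        percent_positive=100.0 * n_pos / n_total,
        analysis_area_mm2=area,
    )


POSITIVE_COLOR = (220, 20, 20)
NEGATIVE_COLOR = (20, 60, 220)
_LEGEND_HEIGHT = 8


def render_markup(img: RGBImage, cells: CellTable, marker: str) -> RGBImage:
    """Overlay detected-cell outlines for visual verification.

    Positive cells are outlined red, negative blue; an 8-px legend strip
    (left half positive color, right half negative) is appended below the
    tile. Deterministic.
    """
    h, w = img.shape
    out = np.vstack([img.pixels, np.full((_LEGEND_HEIGHT, w, 3), 255, dtype=np.uint8)])
    out[h : h + _LEGEND_HEIGHT, : w // 2] = POSITIVE_COLOR
    out[h : h + _LEGEND_HEIGHT, w // 2 :] = NEGATIVE_COLOR
    if len(cells):
        labels = cells.df.get(f"label_{marker}")
        if labels is None:
            raise InputError(f"no labels for marker {marker!r}")
        for _, row in cells.df.iterrows():
            radius = max(2, int(round(math.sqrt(row["nucleus_area_um2"] / math.pi) / cells.mpp)))
            rr, cc = circle_perimeter(
                int(round(row["y"])), int(round(row["x"])), radius, shape=(h, w)
            )
            color = POSITIVE_COLOR if row[f"label_{marker}"] == "positive" else NEGATIVE_COLOR
            out[rr, cc] = color
    return RGBImage(pixels=out, mpp=img.mpp, round_id=img.round_id, name=f"{img.name}_markup")


# convenient re-export for callers building parameter sweeps
def with_threshold(params: DetectionParams, nucleus_threshold: float) -> DetectionParams:
    return replace(params, nucleus_threshold=nucleus_threshold)
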