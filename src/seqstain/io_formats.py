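"""External artifacts and the shared domain types.

Everything the pipeline reads or writes lives here: calibrated bright-field
tiles (TIFF/PNG, 8-bit RGB), landmark point files (CSV), region annotations
(GeoJSON polygons classed tumor / stroma / necrosis / artifact), and the
paired patient cohort table.

Conventions, stated once and used everywhere: coordinates are 0-based and
pixel-centered, x runs rightward (columns), y downward (rows); polygons use
the same frame; microns-per-pixel (``mpp``) converts pixel geometry to
physical area.

Cohort tables are semicolon-delimited text mirroring the column roles of a
clinical characteristics table: per-patient timing, sampling status, prior
and following treatments, a post/pre CD8 density ratio, and per-marker
pre/post value pairs (``<marker>_pre`` / ``<marker>_post``). The decimal
convention is always explicit — many European clinical tables use the comma
— and ``na`` encodes missing. A verbatim fixture of the study cohort ships
with the package (:func:`packaged_table1_path`).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, Polygon, shape
from shapely.ops import unary_union

from .cohort_stats import assign_cohort_group
from .errors import InputError

__all__ = [
    "RGBImage",
    "LandmarkSet",
    "RegionAnnotationSet",
    "PatientRecord",
    "PairedCohort",
    "REGION_CLASSES",
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "read_annotations",
    "write_annotations",
    "read_cohort_table",
    "write_cohort_table",
    "packaged_table1_path",
]

REGION_CLASSES = ("tumor", "stroma", "necrosis", "artifact")


# ---------------------------------------------------------------------------
# Images


@dataclass
class RGBImage:
    """A calibrated 8-bit RGB bright-field tile, the unit of image work."""

    pixels: np.ndarray  # H x W x 3 uint8
    mpp: float  # microns per pixel
    round_id: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError(f"expected HxWx3 pixel array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not (self.mpp > 0):
            raise InputError("mpp must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def read_image(path, mpp: float, round_id: str | None = None) -> RGBImage:
    """Read a TIFF or PNG tile; ``mpp`` is supplied, never read from metadata."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return RGBImage(pixels=arr, mpp=mpp, round_id=round_id, name=path.stem)


def write_image(img: RGBImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img.pixels, photometric="rgb")
    else:
        iio.imwrite(path, img.pixels)


# ---------------------------------------------------------------------------
# Landmarks


@dataclass
class LandmarkSet:
    """Ordered reference marks for one staining round.

    Order defines correspondence: point *i* here matches point *i* of any
    other round's set.
    """

    points: np.ndarray  # N x 2 float, (x, y)
    round_id: str

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InputError("landmark points must be an Nx2 array")
        if len(pts) < 2:
            raise InputError("at least 2 landmarks required")
        if not np.all(np.isfinite(pts)):
            raise InputError("landmark coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


def read_landmarks(path) -> list[LandmarkSet]:
    """Read per-round landmark sets from a ``round_id,index,x,y`` CSV."""
    df = pd.read_csv(path)
    required = {"round_id", "index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"landmark file missing columns: {sorted(missing)}")
    sets = []
    counts = set()
    for rid, grp in df.groupby("round_id", sort=False):
        grp = grp.sort_values("index")
        if grp["index"].duplicated().any():
            raise InputError(f"duplicate landmark index in round {rid!r}")
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        if len(pts) < 2:
            raise InputError("at least 2 landmarks required per round")
        counts.add(len(pts))
        sets.append(LandmarkSet(points=pts, round_id=str(rid)))
    if len(counts) > 1:
        raise InputError("unequal landmark counts across rounds")
    if not sets:
        raise InputError("landmark file contains no rounds")
    return sets


def write_landmarks(sets: list[LandmarkSet], path) -> None:
    rows = []
    for s in sets:
        for i, (x, y) in enumerate(s.points):
            rows.append({"round_id": s.round_id, "index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Region annotations


@dataclass
class RegionAnnotationSet:
    """Classed analysis polygons in pixel coordinates.

    The analysis mask is the union of tumor polygons minus the union of
    stroma, necrosis, and artifact polygons — positive cells are counted
    only inside it.
    """

    polygons: list[tuple[Polygon, str]]
    mpp: float

    def __post_init__(self) -> None:
        if not (self.mpp > 0):
            raise InputError("mpp must be positive")
        for i, (poly, cls) in enumerate(self.polygons):
            if cls not in REGION_CLASSES:
                raise InputError(
                    f"unknown region class {cls!r} (feature {i}); "
                    f"expected one of {REGION_CLASSES}"
                )
            if len(poly.exterior.coords) < 4 or poly.area == 0:
                raise InputError(f"polygon {i} has fewer than 3 vertices or zero area")
            if not poly.is_valid:
                raise InputError(f"polygon {i} ({cls}) is invalid (self-intersecting?)")

    def analysis_geometry(self):
        """Tumor union minus the union of stroma, necrosis, and artifact."""
        tumor = unary_union([p for p, c in self.polygons if c == "tumor"])
        excl = unary_union(
            [p for p, c in self.polygons if c in ("stroma", "necrosis", "artifact")]
        )
        return tumor.difference(excl)

    def analysis_area_mm2(self) -> float:
        return self.analysis_geometry().area * (self.mpp / 1000.0) ** 2

    def contains_points(self, x, y) -> np.ndarray:
        """Boolean mask: which (x, y) pixel points fall in the analysis mask."""
        geom = self.analysis_geometry()
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        import shapely

        return shapely.contains_xy(geom, x, y)

    @classmethod
    def full_tile(cls, shape: tuple[int, int], mpp: float) -> "RegionAnnotationSet":
        """A tumor annotation covering an entire H x W tile."""
        h, w = shape
        poly = Polygon([(-0.5, -0.5), (w - 0.5, -0.5), (w - 0.5, h - 0.5), (-0.5, h - 0.5)])
        return cls(polygons=[(poly, "tumor")], mpp=mpp)


def read_annotations(path, mpp: float) -> RegionAnnotationSet:
    """Read a GeoJSON FeatureCollection of classed polygons."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise InputError("annotation file is not a GeoJSON FeatureCollection")
    polys = []
    for i, feat in enumerate(gj.get("features", [])):
        cls = (feat.get("properties") or {}).get("class")
        if cls not in REGION_CLASSES:
            raise InputError(
                f"feature {i}: unknown class {cls!r}; expected one of {REGION_CLASSES}"
            )
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise InputError(f"feature {i}: geometry must be Polygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise InputError(f"feature {i} ({cls}): self-intersecting polygon")
        polys.append((geom, cls))
    return RegionAnnotationSet(polygons=polys, mpp=mpp)


def write_annotations(regions: RegionAnnotationSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"class": cls},
            "geometry": json.loads(json.dumps(poly.__geo_interface__)),
        }
        for poly, cls in regions.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# Paired cohort table

#: Fixed (non-marker) columns of the cohort table, in write order.
_FIXED_COLUMNS = [
    "pt_id",
    "braf",
    "vax_protocol",
    "site_baseline",
    "site_post",
    "months_surgery_to_vax",
    "months_vax_to_biopsy",
    "sampling_table1",
    "sampling",
    "bor",
    "os_months",
    "biopsy_response",
    "dth",
    "prior_treatments",
    "following_treatments",
    "cd8_ratio_post_pre",
]
_REQUIRED_COLUMNS = {
    "pt_id",
    "months_surgery_to_vax",
    "months_vax_to_biopsy",
    "sampling",
    "prior_treatments",
}
_NUMERIC_FIXED = {"months_surgery_to_vax", "months_vax_to_biopsy", "cd8_ratio_post_pre"}
_SAMPLING_VALUES = {"on_treatment", "post_treatment"}


@dataclass
class PatientRecord:
    """One patient: pre/post marker values plus clinical metadata.

    Missing marker values are NaN, never 0. ``group`` is derived from
    ``prior_treatments`` at read time, not stored in the raw table.
    """

    id: str
    group: str
    sampling: str
    markers: dict[str, tuple[float, float]]  # marker -> (pre, post), NaN = missing
    prior_treatments: str
    following_treatments: str = ""
    months_surgery_to_vax: float = math.nan
    months_vax_to_biopsy: float = math.nan
    best_response: str = ""
    cd8_ratio_post_pre: float = math.nan
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling not in _SAMPLING_VALUES:
            raise InputError(
                f"patient {self.id}: sampling must be one of {sorted(_SAMPLING_VALUES)}"
            )
        for marker, (pre, post) in self.markers.items():
            for v in (pre, post):
                if not math.isnan(v) and v < 0:
                    raise InputError(f"patient {self.id}: negative {marker} value")


@dataclass
class PairedCohort:
    """The paired pre/post cohort; thin query layer over patient records."""

    patients: list[PatientRecord]

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.patients:
            for m in p.markers:
                seen.setdefault(m)
        return list(seen)

    def select(self, group: str | None = None, sampling: str | None = None):
        out = self.patients
        if group is not None:
            out = [p for p in out if p.group == group]
        if sampling is not None:
            out = [p for p in out if p.sampling == sampling]
        return out

    def paired_values(
        self, marker: str, group: str | None = None, sampling: str | None = None
    ) -> tuple[list[str], np.ndarray, np.ndarray]:
        """(ids, pre, post) for patients with both values present."""
        ids, pre, post = [], [], []
        for p in self.select(group=group, sampling=sampling):
            a, b = p.markers.get(marker, (math.nan, math.nan))
            if not (math.isnan(a) or math.isnan(b)):
                ids.append(p.id)
                pre.append(a)
                post.append(b)
        return ids, np.asarray(pre), np.asarray(post)

    def cd8_ratios(
        self, group: str | None = None, sampling: str | None = None
    ) -> np.ndarray:
        vals = [
            p.cd8_ratio_post_pre
            for p in self.select(group=group, sampling=sampling)
            if not math.isnan(p.cd8_ratio_post_pre)
        ]
        return np.asarray(vals)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {
                "pt_id": p.id,
                "group": p.group,
                "sampling": p.sampling,
                "prior_treatments": p.prior_treatments,
                "following_treatments": p.following_treatments,
                "months_surgery_to_vax": p.months_surgery_to_vax,
                "months_vax_to_biopsy": p.months_vax_to_biopsy,
                "bor": p.best_response,
                "cd8_ratio_post_pre": p.cd8_ratio_post_pre,
            }
            for m, (a, b) in p.markers.items():
                row[f"{m}_pre"] = a
                row[f"{m}_post"] = b
            rows.append(row)
        return pd.DataFrame(rows)


def packaged_table1_path(variant: str = "as_printed") -> Path:
    """Path of the packaged study-cohort fixture.

    ``as_printed`` carries every value as the source table prints it;
    ``pt6_pre_zero`` resolves the one ambiguous cell (patient 6's
    pre-treatment PDL1) to 0, the reading consistent with the published
    group means. All headline statistics are identical under either.
    """
    names = {"as_printed": "table1.csv", "pt6_pre_zero": "table1_pt6pre_zero.csv"}
    if variant not in names:
        raise InputError(f"unknown fixture variant {variant!r}")
    return Path(str(resources.files("seqstain").joinpath("data", names[variant])))


def _parse_number(cell: str, decimal: str, row: int, column: str) -> float:
    s = cell.strip()
    if s.lower() in {"", "na", "nan"}:
        return math.nan
    if decimal == "comma":
        if "." in s and "," in s:
            raise InputError(f"row {row}, column {column!r}: mixed decimal separators in {cell!r}")
        s = s.replace(",", ".")
    elif "," in s:
        raise InputError(f"row {row}, column {column!r}: comma in point-decimal cell {cell!r}")
    try:
        return float(s)
    except ValueError:
        raise InputError(f"row {row}, column {column!r}: unparseable numeric cell {cell!r}") from None


def read_cohort_table(path, decimal: str = "comma") -> PairedCohort:
    """Parse a paired cohort table under an explicit decimal convention.

    ``decimal`` is ``"comma"`` or ``"point"`` — no locale guessing. Fields
    are semicolon-separated (the comma being both a decimal separator and a
    list separator inside treatment strings). ``na`` cells become missing
    values; records are always retained. The treatment group is derived per
    patient from the prior-treatments string.
    """
    if decimal not in {"comma", "point"}:
        raise InputError("decimal must be 'comma' or 'point'")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=";")
        if reader.fieldnames is None:
            raise InputError("cohort table has no header")
        columns = [c.strip() for c in reader.fieldnames]
        marker_names = []
        for c in columns:
            if c in _FIXED_COLUMNS:
                continue
            if c.endswith("_pre"):
                m = c[: -len("_pre")]
                if f"{m}_post" not in columns:
                    raise InputError(f"unknown column {c!r} (no matching {m}_post)")
                marker_names.append(m)
            elif c.endswith("_post"):
                if f"{c[:-len('_post')]}_pre" not in columns:
                    raise InputError(f"unknown column {c!r} (no matching _pre)")
            else:
                raise InputError(f"unknown column {c!r}")
        missing = _REQUIRED_COLUMNS - set(columns)
        if missing:
            raise InputError(f"cohort table missing required columns: {sorted(missing)}")

        patients = []
        for rownum, raw in enumerate(reader, start=2):
            row = {(k or "").strip(): (v or "") for k, v in raw.items()}
            markers = {
                m: (
                    _parse_number(row[f"{m}_pre"], decimal, rownum, f"{m}_pre"),
                    _parse_number(row[f"{m}_post"], decimal, rownum, f"{m}_post"),
                )
                for m in marker_names
            }
            num = {
                c: _parse_number(row.get(c, ""), decimal, rownum, c)
                for c in _NUMERIC_FIXED
                if c in columns
            }
            extras = {
                c: row[c]
                for c in columns
                if c in _FIXED_COLUMNS
                and c
                not in _REQUIRED_COLUMNS | _NUMERIC_FIXED | {"pt_id", "bor", "following_treatments"}
            }
            patients.append(
                PatientRecord(
                    id=row["pt_id"].strip(),
                    group=assign_cohort_group(row["prior_treatments"]),
                    sampling=row["sampling"].strip(),
                    markers=markers,
                    prior_treatments=row["prior_treatments"].strip(),
                    following_treatments=row.get("following_treatments", "").strip(),
                    months_surgery_to_vax=num.get("months_surgery_to_vax", math.nan),
                    months_vax_to_biopsy=num.get("months_vax_to_biopsy", math.nan),
                    best_response=row.get("bor", "").strip(),
                    cd8_ratio_post_pre=num.get("cd8_ratio_post_pre", math.nan),
                    extras=extras,
                )
            )
    if not patients:
        raise InputError("cohort table contains no patient rows")
    return PairedCohort(patients=patients)


def _format_number(v: float, decimal: str) -> str:
    if math.isnan(v):
        return "na"
    s = repr(float(v))
    if decimal == "comma":
        s = s.replace(".", ",")
    return s


def write_cohort_table(cohort: PairedCohort, path, decimal: str = "comma") -> None:
    """Write a cohort back to disk; lossless round-trip with :func:`read_cohort_table`."""
    if decimal not in {"comma", "point"}:
        raise InputError("decimal must be 'comma' or 'point'")
    markers = cohort.markers
    header = [
        "pt_id",
        "months_surgery_to_vax",
        "months_vax_to_biopsy",
        "sampling",
        "bor",
        "prior_treatments",
        "following_treatments",
        "cd8_ratio_post_pre",
    ] + [f"{m}_{w}" for m in markers for w in ("pre", "post")]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=";")
        writer.writerow(header)
        for p in cohort.patients:
            row = [
                p.id,
                _format_number(p.months_surgery_to_vax, decimal),
                _format_number(p.months_vax_to_biopsy, decimal),
                p.sampling,
                p.best_response,
                p.prior_treatments,
                p.following_treatments,
                _format_number(p.cd8_ratio_post_pre, decimal),
            ]
            for m in markers:
                pre, post = p.markers.get(m, (math.nan, math.nan))
                row += [_format_number(pre, decimal), _format_number(post, decimal)]
            writer.writerow(row)
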