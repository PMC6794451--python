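"""Color deconvolution of chromogenic bright-field stains.

Beer-Lambert absorption makes stains additive in optical density, so a
pixel's OD vector is a non-negative mixture of per-stain unit "color"
vectors. Inverting the 3x3 stain matrix (hematoxylin counterstain, one
chromogen — red AEC or brown DAB — and a residual completing the basis)
recovers per-stain concentration maps from an RGB tile. Default stain
vectors are the published Ruifrok-Johnston values; override them when the
staining protocol differs.

OD is computed per channel as -log10(max(I, 1)/I0) with I0 = 255, so white
has OD 0 and the representable maximum is log10(255) ~= 2.407. Negative
concentrations (pixels slightly outside the stain span) are preserved here
for exact invertibility and clipped to 0 only when measured downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io_formats import RGBImage

__all__ = [
    "ODImage",
    "StainMatrix",
    "StainChannels",
    "OD_MAX",
    "default_stain_matrix",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "recompose",
    "od_sum",
    "pseudo_composite",
]

OD_MAX = float(np.log10(255.0))

STAIN_ROLES = ("hematoxylin", "chromogen", "residual")

# Ruifrok-Johnston OD-space stain vectors (RGB order), before normalization.
_RUIFROK = {
    "hematoxylin": (0.650, 0.704, 0.286),
    "dab": (0.268, 0.570, 0.776),
    "aec": (0.2743, 0.6796, 0.6803),
}


@dataclass
class ODImage:
    """Per-channel optical density of a tile; geometry matches the source."""

    od: np.ndarray  # H x W x 3, >= 0
    mpp: float

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        if od.ndim != 3 or od.shape[2] != 3:
            raise InputError("OD array must be HxWx3")
        if not np.all(np.isfinite(od)):
            raise InputError("OD values must be finite")
        self.od = od


@dataclass(frozen=True)
class StainMatrix:
    """Rows are unit OD-RGB vectors for (hematoxylin, chromogen, residual)."""

    rows: np.ndarray  # 3 x 3
    chromogen_kind: str  # "AEC" or "DAB"

    def __post_init__(self) -> None:
        m = np.asarray(self.rows, dtype=float)
        if m.shape != (3, 3):
            raise InputError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InputError("stain vectors must be unit-normalized")
        if abs(np.linalg.det(m)) < 1e-12:
            raise InputError("stain matrix is singular")
        if self.chromogen_kind not in {"AEC", "DAB"}:
            raise InputError("chromogen_kind must be 'AEC' or 'DAB'")
        object.__setattr__(self, "rows", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.rows)


@dataclass
class StainChannels:
    """Per-pixel stain concentrations (OD units along each stain vector)."""

    conc: np.ndarray  # H x W x 3 ordered (hematoxylin, chromogen, residual)
    mpp: float

    def channel(self, role: str, clip: bool = True) -> np.ndarray:
        if role not in STAIN_ROLES:
            raise InputError(f"unknown stain role {role!r}")
        ch = self.conc[..., STAIN_ROLES.index(role)]
        return np.clip(ch, 0.0, None) if clip else ch


def default_stain_matrix(stains: str = "h-aec") -> StainMatrix:
    """Stain matrix for ``"h-aec"`` or ``"h-dab"`` with residual completed
    by the (normalized) cross product of the two stain vectors."""
    key = stains.lower()
    if key not in {"h-aec", "h-dab"}:
        raise InputError(f"unknown stain pair {stains!r}")
    chrom_name = key.split("-")[1]
    h = np.asarray(_RUIFROK["hematoxylin"], dtype=float)
    c = np.asarray(_RUIFROK[chrom_name], dtype=float)
    h = h / np.linalg.norm(h)
    c = c / np.linalg.norm(c)
    r = np.cross(h, c)
    r = r / np.linalg.norm(r)
    return StainMatrix(rows=np.stack([h, c, r]), chromogen_kind=chrom_name.upper())


def rgb_to_od(img: RGBImage, i0: float = 255.0) -> ODImage:
    """Per-channel optical density: -log10(max(I, 1)/i0).

    The 1-intensity floor bounds OD at saturation; brighter pixels never
    have higher OD.
    """
    if not (i0 > 0):
        raise InputError("i0 must be positive")
    i = np.maximum(img.pixels.astype(float), 1.0)
    return ODImage(od=-np.log10(i / i0), mpp=img.mpp)


def od_to_rgb(od: ODImage, i0: float = 255.0) -> RGBImage:
    """Invert :func:`rgb_to_od` (up to integer rounding of intensities)."""
    i = i0 * np.power(10.0, -np.asarray(od.od, dtype=float))
    return RGBImage(pixels=np.clip(np.rint(i), 0, 255).astype(np.uint8), mpp=od.mpp)


def deconvolve(od: ODImage, sm: StainMatrix) -> StainChannels:
    """Unmix an OD image into per-stain concentrations (od = conc @ rows)."""
    conc = np.asarray(od.od) @ sm.inverse
    return StainChannels(conc=conc, mpp=od.mpp)


def recompose(
    ch: StainChannels, sm: StainMatrix, subset: tuple[str, ...] = STAIN_ROLES
) -> ODImage:
    """Rebuild OD from a subset of stains; the full subset inverts
    :func:`deconvolve` exactly."""
    if not subset:
        raise InputError("subset must be non-empty")
    unknown = [r for r in subset if r not in STAIN_ROLES]
    if unknown:
        raise InputError(f"unknown stain role(s): {unknown}")
    od = np.zeros_like(ch.conc)
    for role in subset:
        k = STAIN_ROLES.index(role)
        od += ch.conc[..., k][..., None] * sm.rows[k][None, None, :]
    return ODImage(od=od, mpp=ch.mpp)


def od_sum(od: ODImage) -> np.ndarray:
    """Sum of the three per-channel ODs — the detection signal that is
    robust to weak hematoxylin counterstain."""
    return np.asarray(od.od).sum(axis=2)


def pseudo_composite(
    channels: list[tuple[np.ndarray, tuple[int, int, int]]],
    mpp: float = 1.0,
    normalize: bool = True,
) -> RGBImage:
    """Additive pseudo-color blend of concentration maps.

    Each (map, display color) pair contributes ``map/max * color`` (or the
    raw map if ``normalize`` is off); contributions add and clip to
    [0, 255]. All maps must share one shape. Deterministic.
    """
    if not channels:
        raise InputError("at least one channel required")
    shape = np.asarray(channels[0][0]).shape
    out = np.zeros(shape + (3,), dtype=float)
    for arr, color in channels:
        arr = np.clip(np.asarray(arr, dtype=float), 0.0, None)
        if arr.shape != shape:
            raise InputError("channel shape mismatch in pseudo_composite")
        peak = arr.max()
        scaled = arr / peak if (normalize and peak > 0) else arr
        out += scaled[..., None] * np.asarray(color, dtype=float)[None, None, :]
    return RGBImage(pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8), mpp=mpp)
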