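"""Landmark-based co-registration of sequential staining rounds.

Each staining/destaining/stripping cycle can translate, rotate, and
uniformly dilate or shrink the section, so rounds are aligned with a
similarity transform (scale * rotation + translation) fitted to
corresponding reference marks by closed-form least squares (Umeyama's
solution of the orthogonal Procrustes problem, reflection excluded — slides
do not mirror). An affine model is available for anisotropic deformation.

A derivative-free iterative refinement polishes the landmark fit by
coordinate descent on the mean squared difference of the hematoxylin OD
channels over the image overlap; its cost never increases. Aligned rounds
are resampled into the reference frame (bilinear interpolation, white
background fill — white is OD-neutral downstream) and assembled into a
z-stack for cross-round comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .errors import InputError
from .io_formats import LandmarkSet, RGBImage

__all__ = [
    "Transform2D",
    "RegistrationReport",
    "estimate_transform",
    "registration_error",
    "refine_transform",
    "warp_image",
    "build_stack",
]


@dataclass(frozen=True)
class Transform2D:
    """A 2D point map stored as a 3x3 homogeneous matrix acting on (x, y)."""

    matrix: np.ndarray
    model: str = "similarity"  # "similarity" or "affine"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InputError("transform matrix must be 3x3")
        if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=1e-12):
            raise InputError("last homogeneous row must be [0, 0, 1]")
        if abs(np.linalg.det(m[:2, :2])) < 1e-15:
            raise InputError("singular linear part")
        if self.model not in {"similarity", "affine"}:
            raise InputError(f"unknown transform model {self.model!r}")
        object.__setattr__(self, "matrix", m)

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls, model: str = "similarity") -> "Transform2D":
        return cls(np.eye(3), model=model)

    @classmethod
    def from_similarity(
        cls, scale: float, rotation: float, tx: float, ty: float
    ) -> "Transform2D":
        if not (scale > 0):
            raise InputError("similarity scale must be positive")
        c, s = math.cos(rotation), math.sin(rotation)
        m = np.array(
            [[scale * c, -scale * s, tx], [scale * s, scale * c, ty], [0.0, 0.0, 1.0]]
        )
        return cls(m, model="similarity")

    # -- parameters ---------------------------------------------------------

    @property
    def scale(self) -> float:
        a = self.matrix[:2, :2]
        return float(math.sqrt(abs(np.linalg.det(a))))

    @property
    def rotation(self) -> float:
        return float(math.atan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def translation(self) -> tuple[float, float]:
        return float(self.matrix[0, 2]), float(self.matrix[1, 2])

    # -- algebra ------------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    def compose(self, other: "Transform2D") -> "Transform2D":
        """self after other: (self @ other)(p) = self(other(p))."""
        model = "similarity" if self.model == other.model == "similarity" else "affine"
        return Transform2D(self.matrix @ other.matrix, model=model)

    def invert(self) -> "Transform2D":
        return Transform2D(np.linalg.inv(self.matrix), model=self.model)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"model": self.model, "matrix": self.matrix.reshape(-1).tolist()}, indent=2
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "Transform2D":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        return cls(np.asarray(obj["matrix"], dtype=float).reshape(3, 3), model=obj["model"])


@dataclass(frozen=True)
class RegistrationReport:
    transform: Transform2D
    rmse_px: float
    n_landmarks: int
    iterations: int = 0
    cost_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.rmse_px < 0 or self.iterations < 0:
            raise InputError("rmse and iteration count must be non-negative")


# ---------------------------------------------------------------------------
# Landmark least squares


def _check_correspondence(moving: LandmarkSet, fixed: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    src = np.asarray(moving.points, dtype=float)
    dst = np.asarray(fixed.points, dtype=float)
    if src.shape != dst.shape:
        raise InputError("unequal landmark counts between rounds")
    return src, dst


def estimate_transform(
    moving: LandmarkSet, fixed: LandmarkSet, model: str = "similarity"
) -> Transform2D:
    """Global least-squares transform mapping moving landmarks onto fixed.

    Minimizes sum_i ||T(m_i) - f_i||^2 in closed form: Umeyama's similarity
    solution (SVD of the cross-covariance, determinant forced positive) or
    the affine normal equations. Degenerate configurations — coincident
    points, or collinear points for the affine model — are rejected.
    """
    src, dst = _check_correspondence(moving, fixed)
    n = len(src)
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    cs = src - mu_s
    cd = dst - mu_d
    var_s = float((cs**2).sum() / n)

    if model == "similarity":
        if n < 2 or var_s == 0.0:
            raise InputError("similarity fit needs >= 2 distinct points")
        cov = cd.T @ cs / n
        u, d, vt = np.linalg.svd(cov)
        s_fix = np.eye(2)
        if np.linalg.det(u) * np.linalg.det(vt) < 0:  # exclude reflections
            s_fix[1, 1] = -1.0
        r = u @ s_fix @ vt
        scale = float(np.trace(np.diag(d) @ s_fix) / var_s)
        if scale <= 0:
            raise InputError("degenerate landmark configuration (non-positive scale)")
        t = mu_d - scale * (r @ mu_s)
        m = np.eye(3)
        m[:2, :2] = scale * r
        m[:2, 2] = t
        return Transform2D(m, model="similarity")

    if model == "affine":
        if n < 3:
            raise InputError("affine fit needs >= 3 points")
        # rank check: points must not be collinear
        if np.linalg.matrix_rank(cs, tol=1e-9 * max(1.0, np.abs(cs).max())) < 2:
            raise InputError("affine fit needs non-collinear points")
        a = np.hstack([src, np.ones((n, 1))])
        coef, *_ = np.linalg.lstsq(a, dst, rcond=None)
        m = np.eye(3)
        m[:2, :2] = coef[:2].T
        m[:2, 2] = coef[2]
        return Transform2D(m, model="affine")

    raise InputError(f"unknown model {model!r}")


def registration_error(t: Transform2D, moving: LandmarkSet, fixed: LandmarkSet) -> float:
    """Root-mean-square landmark residual ||T(m_i) - f_i|| in pixels."""
    src, dst = _check_correspondence(moving, fixed)
    res = t.apply(src) - dst
    return float(np.sqrt((res**2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Image warping


def warp_image(img: RGBImage, t: Transform2D, out_shape: tuple[int, int] | None = None) -> RGBImage:
    """Resample ``img`` under ``t`` (bilinear, white background fill).

    ``t`` maps source pixel coordinates into the output frame; resampling
    uses its inverse. Output pixels mapping outside the source are filled
    with bright-field white (255, 255, 255).
    """
    if out_shape is None:
        out_shape = img.shape
    inv = t.invert().matrix
    h, w = out_shape
    yy, xx = np.mgrid[0:h, 0:w]
    sx = inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]
    sy = inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]
    out = np.empty((h, w, 3), dtype=np.uint8)
    for c in range(3):
        ch = ndi.map_coordinates(
            img.pixels[..., c].astype(float),
            [sy, sx],
            order=1,
            mode="constant",
            cval=255.0,
        )
        out[..., c] = np.clip(np.rint(ch), 0, 255).astype(np.uint8)
    return RGBImage(pixels=out, mpp=img.mpp, round_id=img.round_id, name=img.name)


def _hematoxylin_od(img: RGBImage) -> np.ndarray:
    from .stain_deconvolution import default_stain_matrix, deconvolve, rgb_to_od

    sm = default_stain_matrix("h-dab")
    conc = deconvolve(rgb_to_od(img), sm)
    return np.clip(conc.conc[..., 0], 0.0, None)


def _alignment_cost(fixed_h: np.ndarray, moving_h: np.ndarray, t: Transform2D) -> float:
    """Mean squared hematoxylin-OD difference over the warped overlap."""
    h, w = fixed_h.shape
    inv = t.invert().matrix
    yy, xx = np.mgrid[0:h, 0:w]
    sx = inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]
    sy = inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]
    mh, mw = moving_h.shape
    inside = (sx >= 0) & (sx <= mw - 1) & (sy >= 0) & (sy <= mh - 1)
    if not inside.any():
        raise InputError("empty overlap between images at this transform")
    warped = ndi.map_coordinates(moving_h, [sy, sx], order=1, mode="constant", cval=0.0)
    diff = (warped - fixed_h)[inside]
    return float((diff**2).mean())


def refine_transform(
    fixed_img: RGBImage,
    moving_img: RGBImage,
    t0: Transform2D,
    max_iter: int = 50,
    tol: float = 1e-6,
    moving_landmarks: LandmarkSet | None = None,
    fixed_landmarks: LandmarkSet | None = None,
) -> RegistrationReport:
    """Fine alignment by deterministic coordinate descent.

    Starting at ``t0``, the four similarity parameters (scale, rotation,
    tx, ty) are perturbed one at a time with a step-halving schedule,
    keeping only moves that lower the mean squared hematoxylin-OD
    difference over the overlap. The cost sequence is non-increasing by
    construction; iteration stops when the sweep improvement falls below
    ``tol`` or ``max_iter`` sweeps are reached.
    """
    if abs(fixed_img.mpp - moving_img.mpp) > 1e-12:
        raise InputError("fixed and moving images must share mpp")
    fixed_h = _hematoxylin_od(fixed_img)
    moving_h = _hematoxylin_od(moving_img)

    params = np.array(
        [t0.scale, t0.rotation, t0.translation[0], t0.translation[1]], dtype=float
    )
    steps = np.array([0.02, 0.01, 2.0, 2.0])  # scale, radians, px, px

    def cost_of(p: np.ndarray) -> float:
        return _alignment_cost(
            fixed_h, moving_h, Transform2D.from_similarity(p[0], p[1], p[2], p[3])
        )

    best = cost_of(params)
    history = [best]
    iterations = 0
    for _ in range(max_iter):
        start = best
        improved = False
        for i in range(4):
            for sign in (1.0, -1.0):
                trial = params.copy()
                trial[i] += sign * steps[i]
                if trial[0] <= 0:
                    continue
                c = cost_of(trial)
                if c < best - 1e-15:
                    best, params, improved = c, trial, True
                    break
        history.append(best)
        if improved:
            iterations += 1
            if start - best < tol:
                break
        else:
            # no move helped at this resolution: refine the step grid
            steps /= 2.0
            if np.all(steps < np.array([1e-5, 1e-5, 1e-3, 1e-3])):
                break

    t = Transform2D.from_similarity(*params)
    if moving_landmarks is not None and fixed_landmarks is not None:
        rmse = registration_error(t, moving_landmarks, fixed_landmarks)
        n_lm = len(moving_landmarks)
    else:
        rmse = math.sqrt(best)  # RMS OD difference stands in when no marks given
        n_lm = 0
    return RegistrationReport(
        transform=t,
        rmse_px=rmse,
        n_landmarks=n_lm,
        iterations=iterations,
        cost_history=tuple(history),
    )


def build_stack(
    rounds: list[RGBImage],
    transforms: dict[str, Transform2D],
    reference: str,
) -> list[RGBImage]:
    """Warp every round into the reference frame and return the z-stack.

    ``transforms[round_id]`` maps that round's coordinates into the
    reference frame; the reference round passes through unchanged.
    """
    ref = next((r for r in rounds if r.round_id == reference), None)
    if ref is None:
        raise InputError(f"reference round {reference!r} not present")
    out = []
    for r in rounds:
        if r.round_id == reference:
            out.append(r)
            continue
        t = transforms.get(r.round_id)
        if t is None:
            raise InputError(f"missing transform for round {r.round_id!r}")
        out.append(warp_image(r, t, out_shape=ref.shape))
    return out
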