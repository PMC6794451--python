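"""Deterministic synthetic inputs: multi-round stained tiles and cohorts.

The slide generator emulates what the imaging pipeline consumes: a field of
non-overlapping, anti-aliased disk nuclei counterstained with hematoxylin on
a pale background, per-marker chromogen (AEC/DAB) deposited over the cell
footprint of positive cells, configurable marker co-expression
(P(B+ | A+)), and one image per staining round, each rendered after a known
similarity transform (the staining/destaining cycle's dilation, rotation,
and shift) with additive Gaussian intensity noise. Rendering goes through
the exact Beer-Lambert forward model and the same stain vectors the
deconvolution module inverts, so ground truth is unambiguous: true
centroids, labels, transforms, and landmark positions are all returned.

The cohort generator emulates a paired pre/post marker table: pre values are
log-normal (median 10, log-sd 0.5 by default — the scale of percent-positive
readings), post = pre + effect + Gaussian noise floored at 0, patients carry
prior-treatment strings drawn from a fixed naive/immuno mix, and missingness
is explicit. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, SeqstainError
from .io_formats import LandmarkSet, PairedCohort, PatientRecord, RGBImage
from .registration import Transform2D
from .stain_deconvolution import ODImage, StainMatrix, default_stain_matrix, od_to_rgb

__all__ = [
    "SlideSimParams",
    "GroundTruth",
    "generate_multiround_slide",
    "render_round_od",
    "generate_cohort",
]


@dataclass(frozen=True)
class SlideSimParams:
    """Configuration of the synthetic multi-round slide.

    ``rounds`` maps round id -> stained marker (None = counterstain only);
    ``round_transforms`` maps round id -> (scale, rotation rad, tx px, ty px)
    carrying that round's coordinates into the reference frame. The first
    round listed is the reference and must have the identity transform.
    """

    shape: tuple[int, int] = (384, 384)
    mpp: float = 0.5
    n_cells: int = 120
    nucleus_radius_um: float = 3.0
    nucleus_radius_sd_um: float = 0.4
    marker_fractions: dict[str, float] = field(
        default_factory=lambda: {"CD8": 0.4, "GZMB": 0.3}
    )
    coexpression: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("CD8", "GZMB"): 0.6}
    )
    rounds: tuple[tuple[str, str | None], ...] = (("r1", "CD8"), ("r2", "GZMB"))
    round_transforms: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {"r1": (1.0, 0.0, 0.0, 0.0), "r2": (1.01, 0.01, 2.0, -1.5)}
    )
    stains: str = "h-aec"
    hematoxylin_conc: float = 0.8
    chromogen_conc: float = 0.7
    cell_radius_factor: float = 1.6  # chromogen footprint = factor * nucleus radius
    noise_sd: float = 2.0  # additive intensity noise, 8-bit levels
    n_landmarks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for m, f in self.marker_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise InputError(f"marker fraction for {m!r} outside [0, 1]")
        for pair, p in self.coexpression.items():
            if not (0.0 <= p <= 1.0):
                raise InputError(f"co-expression P for {pair} outside [0, 1]")
        for rid, (s, *_rest) in self.round_transforms.items():
            if s <= 0:
                raise InputError(f"round {rid!r}: scale must be positive")
        if self.n_cells < 0 or self.n_landmarks < 2:
            raise InputError("need n_cells >= 0 and >= 2 landmarks")


@dataclass
class GroundTruth:
    """Everything the generator knows: the oracle for every downstream test."""

    centers_ref: np.ndarray  # N x 2 (x, y) px in the reference frame
    radii_um: np.ndarray  # N
    labels: dict[str, np.ndarray]  # marker -> bool array of length N
    transforms: dict[str, Transform2D]  # round id -> (round -> reference) map
    landmarks_ref: np.ndarray  # L x 2 px
    round_marker: dict[str, str | None]


def _draw_labels(params: SlideSimParams, rng: np.random.Generator, n: int):
    labels: dict[str, np.ndarray] = {}
    for marker, frac in params.marker_fractions.items():
        cond = next(
            ((a, p) for (a, b), p in params.coexpression.items() if b == marker and a in labels),
            None,
        )
        if cond is None:
            labels[marker] = rng.random(n) < frac
        else:
            a, p_given = cond
            f_a = params.marker_fractions[a]
            # choose P(B+|A-) so the marginal fraction is preserved
            q = 0.0 if f_a >= 1.0 else (frac - f_a * p_given) / (1.0 - f_a)
            q = min(max(q, 0.0), 1.0)
            u = rng.random(n)
            labels[marker] = np.where(labels[a], u < p_given, u < q)
    return labels


def _place_cells(params: SlideSimParams, rng: np.random.Generator):
    h, w = params.shape
    radii_um = np.clip(
        rng.normal(params.nucleus_radius_um, params.nucleus_radius_sd_um, params.n_cells),
        0.5 * params.nucleus_radius_um,
        2.0 * params.nucleus_radius_um,
    )
    radii_px = radii_um / params.mpp
    margin = float(radii_px.max() * params.cell_radius_factor + 12.0) if params.n_cells else 0.0
    if params.n_cells and (w - 2 * margin <= 0 or h - 2 * margin <= 0):
        raise InputError("tile too small for the requested cell geometry")
    centers: list[tuple[float, float]] = []
    budget = 300 * max(params.n_cells, 1)
    for i in range(params.n_cells):
        placed = False
        for _ in range(budget // max(params.n_cells, 1)):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            ok = True
            for j, (cx, cy) in enumerate(centers):
                min_d = (radii_px[i] + radii_px[j]) * params.cell_radius_factor + 2.0
                if (x - cx) ** 2 + (y - cy) ** 2 < min_d**2:
                    ok = False
                    break
            if ok:
                centers.append((x, y))
                placed = True
                break
        if not placed:
            raise SeqstainError(
                "cell density too high: could not place cells without overlap"
            )
    return np.asarray(centers, dtype=float).reshape(-1, 2), radii_um


def _disk_coverage(shape, cx, cy, r_px):
    """Anti-aliased disk: per-pixel coverage in [0, 1] with a 1-px soft edge."""
    h, w = shape
    x0, x1 = max(0, int(cx - r_px - 2)), min(w, int(cx + r_px + 3))
    y0, y1 = max(0, int(cy - r_px - 2)), min(h, int(cy + r_px + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    return (slice(y0, y1), slice(x0, x1)), np.clip(r_px + 0.5 - d, 0.0, 1.0)


def render_round_od(
    params: SlideSimParams, truth: GroundTruth, round_id: str, sm: StainMatrix
) -> ODImage:
    """Noiseless Beer-Lambert OD image of one round.

    The scene is drawn in the round's own frame (the inverse of the truth
    transform applied to reference positions): hematoxylin over each
    nucleus, chromogen over the whole cell footprint of cells positive for
    the round's marker.
    """
    marker = truth.round_marker[round_id]
    t_inv = truth.transforms[round_id].invert()
    centers = t_inv.apply(truth.centers_ref) if len(truth.centers_ref) else truth.centers_ref
    scale = truth.transforms[round_id].invert().scale  # round-frame px per ref px

    h, w = params.shape
    hema = np.zeros((h, w))
    chrom = np.zeros((h, w))
    for i, (cx, cy) in enumerate(centers):
        r_px = truth.radii_um[i] / params.mpp * scale
        sl, cov = _disk_coverage((h, w), cx, cy, r_px)
        np.maximum(hema[sl], params.hematoxylin_conc * cov, out=hema[sl])
        if marker is not None and truth.labels[marker][i]:
            sl2, cov2 = _disk_coverage((h, w), cx, cy, r_px * params.cell_radius_factor)
            np.maximum(chrom[sl2], params.chromogen_conc * cov2, out=chrom[sl2])
    od = hema[..., None] * sm.rows[0][None, None, :] + chrom[..., None] * sm.rows[1][None, None, :]
    return ODImage(od=od, mpp=params.mpp)


def generate_multiround_slide(
    params: SlideSimParams = SlideSimParams(),
) -> tuple[list[RGBImage], list[LandmarkSet], GroundTruth]:
    """Render every staining round plus its landmarks and the ground truth.

    Deterministic for a given seed (same seed -> byte-identical images).
    Landmark files carry the exact fiducial positions, so landmark-based
    registration can be checked for exact parameter recovery.
    """
    rng = np.random.default_rng(params.seed)
    sm = default_stain_matrix(params.stains)
    centers, radii_um = _place_cells(params, rng)
    labels = _draw_labels(params, rng, len(centers))

    transforms = {
        rid: Transform2D.from_similarity(*params.round_transforms[rid])
        for rid, _ in params.rounds
    }
    ref_id = params.rounds[0][0]
    if not np.allclose(transforms[ref_id].matrix, np.eye(3), atol=1e-12):
        raise InputError("reference round must carry the identity transform")

    h, w = params.shape
    inset = 15.0
    base = np.array(
        [(inset, inset), (w - inset, inset), (w - inset, h - inset), (inset, h - inset)]
    )
    if params.n_landmarks > 4:
        extra = rng.uniform(inset, min(w, h) - inset, size=(params.n_landmarks - 4, 2))
        base = np.vstack([base, extra])
    landmarks_ref = base[: params.n_landmarks]

    truth = GroundTruth(
        centers_ref=centers,
        radii_um=radii_um,
        labels=labels,
        transforms=transforms,
        landmarks_ref=landmarks_ref,
        round_marker={rid: m for rid, m in params.rounds},
    )

    rounds: list[RGBImage] = []
    landmark_sets: list[LandmarkSet] = []
    for rid, _marker in params.rounds:
        od = render_round_od(params, truth, rid, sm)
        img = od_to_rgb(od)
        if params.noise_sd > 0:
            noisy = img.pixels.astype(float) + rng.normal(0.0, params.noise_sd, img.pixels.shape)
            img = RGBImage(
                pixels=np.clip(np.rint(noisy), 0, 255).astype(np.uint8),
                mpp=params.mpp,
            )
        img.round_id = rid
        img.name = f"synthetic_{rid}"
        rounds.append(img)
        landmark_sets.append(
            LandmarkSet(points=transforms[rid].invert().apply(landmarks_ref), round_id=rid)
        )
    return rounds, landmark_sets, truth


# ---------------------------------------------------------------------------
# Cohort generator

_NAIVE_PRIORS = ("No", "CT", "RT")
_IMMUNO_PRIORS = ("BioCT", "Ipi", "Biot")


def generate_cohort(
    n_patients: int = 16,
    markers: tuple[str, ...] = ("pdl1",),
    paired_effect: dict[str, float] | float = 0.0,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    pre_log_mean: float = math.log(10.0),
    pre_log_sd: float = 0.5,
    immuno_fraction: float = 7 / 16,
) -> PairedCohort:
    """Simulate a paired pre/post cohort with a known additive effect.

    Pre values are log-normal(``pre_log_mean``, ``pre_log_sd``); post = pre
    + effect + N(0, noise_sd), floored at 0 (with the default scale the
    floor is essentially never active, so a zero effect yields an exactly
    symmetric null). Prior-treatment strings are drawn from a fixed
    naive/immuno mix so group stratification is exercised end to end.
    """
    if n_patients < 3:
        raise InputError("need at least 3 patients")
    if not (0.0 <= missing_rate < 1.0):
        raise InputError("missing_rate must be in [0, 1)")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    if isinstance(paired_effect, (int, float)):
        paired_effect = {m: float(paired_effect) for m in markers}

    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n_patients):
        immuno = rng.random() < immuno_fraction
        pool = _IMMUNO_PRIORS if immuno else _NAIVE_PRIORS
        prior = pool[int(rng.integers(len(pool)))]
        marker_vals = {}
        for m in markers:
            pre = float(rng.lognormal(pre_log_mean, pre_log_sd))
            post = max(0.0, pre + paired_effect.get(m, 0.0) + float(rng.normal(0.0, noise_sd)))
            if missing_rate and rng.random() < missing_rate:
                pre = math.nan
            if missing_rate and rng.random() < missing_rate:
                post = math.nan
            marker_vals[m] = (pre, post)
        patients.append(
            PatientRecord(
                id=str(i + 1),
                group="immuno_treated" if immuno else "naive_ct_rt",
                sampling="post_treatment" if rng.random() < 0.2 else "on_treatment",
                markers=marker_vals,
                prior_treatments=prior,
                months_surgery_to_vax=float(rng.integers(0, 30)),
                months_vax_to_biopsy=float(rng.integers(3, 25)),
                best_response=str(rng.choice(["CR", "PR", "SD", "PD"])),
                cd8_ratio_post_pre=float(rng.lognormal(0.0, 0.7)),
            )
        )
    return PairedCohort(patients=patients)
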