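"""Paired cohort statistics for pre/post-treatment marker comparisons.

Implements the statistical layer used to compare tumor-infiltrating
lymphocyte densities and PDL1 percent-positivity between matched pre- and
post-vaccine biopsies:

* exact two-sided Wilcoxon signed-rank test (full sign-assignment
  enumeration via dynamic programming, normal approximation above n = 25);
* Spearman rank correlation (midrank Pearson rho, t-distribution p);
* descriptive statistics reported as mean +/- SEM;
* post/pre ratios, RECIST-style lesion response classes, and treatment-group
  stratification from prior-treatment strings.

No multiple-testing correction is applied anywhere in this module; each test
is reported at its nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .errors import InputError

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "Descriptives",
    "wilcoxon_signed_rank",
    "spearman",
    "descriptives",
    "post_pre_ratio",
    "classify_lesion_response",
    "assign_cohort_group",
    "IMMUNO_TOKENS",
    "NAIVE_TOKENS",
]

#: Largest n for which the exact signed-rank null distribution is enumerated.
EXACT_N_MAX = 25


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of a paired Wilcoxon signed-rank test.

    ``w_statistic`` is the smaller of the positive and negative signed-rank
    sums, the convention used by common desktop statistics packages.
    """

    n_used: int
    w_statistic: float
    p_two_sided: float
    method: str  # "exact" or "normal_approx"

    def __post_init__(self) -> None:
        n = self.n_used
        if not (0.0 <= self.w_statistic <= n * (n + 1) / 2):
            raise ValueError("W outside [0, n(n+1)/2]")
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError("p outside (0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with a two-sided p-value."""

    rho: float
    p_two_sided: float
    n: int


@dataclass(frozen=True)
class Descriptives:
    """Summary statistics; ``sem`` is sd/sqrt(n) with the n-1 denominator."""

    n: int
    mean: float
    sem: float | None
    median: float
    min: float
    max: float


def _drop_missing_pairs(pre, post) -> tuple[np.ndarray, np.ndarray]:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise InputError("pre and post must have equal length")
    keep = ~(np.isnan(pre) | np.isnan(post))
    return pre[keep], post[keep]


def signed_rank_cdf_counts(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Null distribution of the positive signed-rank sum W+.

    Returns ``(counts, denom)`` where ``counts[k]`` is the number of the
    ``denom = 2**n`` equiprobable sign assignments whose W+ equals ``k/2``
    (ranks are doubled internally so that midranks stay on an integer grid).
    """
    doubled = np.rint(2.0 * np.asarray(ranks, dtype=float)).astype(np.int64)
    if not np.allclose(2.0 * np.asarray(ranks, float), doubled, atol=1e-9):
        raise ValueError("midranks are not on a half-integer grid")
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts, 2 ** len(doubled)


def wilcoxon_signed_rank(pre, post) -> PairedTestResult:
    """Two-tailed Wilcoxon signed-rank test on paired values.

    Missing values (NaN) are removed pairwise; zero differences are dropped
    (Wilcoxon's original treatment); absolute differences are midranked.
    For n <= 25 the two-sided p is exact: 2 * P(W+ <= min(W+, W-)) under
    full enumeration of the 2^n sign assignments, capped at 1. Above 25 a
    normal approximation with continuity and tie correction is used.

    Raises
    ------
    InputError
        If no nonzero differences remain ("test undefined").
    """
    pre, post = _drop_missing_pairs(pre, post)
    d = post - pre
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise InputError("test undefined: all paired differences are zero")
    ranks = _stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)

    if n <= EXACT_N_MAX:
        counts, denom = signed_rank_cdf_counts(ranks)
        # counts index k corresponds to W+ = k/2 (doubled-rank grid)
        k = int(round(2.0 * w))
        tail = counts[: k + 1].sum() / denom
        p = min(1.0, 2.0 * tail)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, t_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((t_counts**3 - t_counts).sum()) / 48.0)
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w - mu + 0.5) / sigma  # w <= mu by construction
        p = min(1.0, 2.0 * _stats.norm.cdf(z))
        method = "normal_approx"
    return PairedTestResult(n_used=n, w_statistic=w, p_two_sided=p, method=method)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with two-sided p-value.

    rho is the product-moment correlation of midranks. The p-value uses
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom; when
    |rho| = 1 the exact permutation bound 2/n! is reported instead.
    """
    x, y = _drop_missing_pairs(x, y)
    n = len(x)
    if n < 3:
        raise InputError("spearman requires at least 3 complete pairs")
    rx = _stats.rankdata(x)
    ry = _stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise InputError("spearman undefined: zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-12:
        rho = math.copysign(1.0, rho)
        p = min(1.0, 2.0 / math.factorial(n))
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(_stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_two_sided=p, n=n)


def descriptives(values) -> Descriptives:
    """n, mean, SEM, median (mean of central two for even n), min, max."""
    v = np.asarray(values, dtype=float)
    v = np.sort(v[~np.isnan(v)])  # sorting makes results input-order invariant
    n = len(v)
    if n == 0:
        raise InputError("descriptives undefined on empty input")
    sem = float(np.std(v, ddof=1) / math.sqrt(n)) if n >= 2 else None
    return Descriptives(
        n=n,
        mean=float(np.mean(v)),
        sem=sem,
        median=float(np.median(v)),
        min=float(np.min(v)),
        max=float(np.max(v)),
    )


def post_pre_ratio(pre: float, post: float) -> float | None:
    """post/pre ratio; ``None`` (explicitly undefined) when pre is 0."""
    if pre < 0 or post < 0:
        raise InputError("marker values must be non-negative")
    if pre == 0:
        return None
    return post / pre


def classify_lesion_response(baseline_diameter: float, post_diameter: float) -> str:
    """RECIST-style class from longest-diameter change.

    regressing if the change is <= -30%, progressing if >= +20%, else stable.
    """
    if baseline_diameter <= 0 or post_diameter <= 0:
        raise InputError("diameters must be positive")
    delta_pct = 100.0 * (post_diameter - baseline_diameter) / baseline_diameter
    if delta_pct <= -30.0:
        return "regressing"
    if delta_pct >= 20.0:
        return "progressing"
    return "stable"


#: Prior-treatment tokens marking previous immune-modulating therapy
#: (cytokines or anti-CTLA4).
IMMUNO_TOKENS = frozenset({"ipi", "biot", "bioct", "il-2", "ifn"})
#: Tokens compatible with the treatment-naive / chemo / radiotherapy group.
NAIVE_TOKENS = frozenset({"no", "ct", "rt"})


def assign_cohort_group(prior_treatments: str) -> str:
    """Stratify a patient by the therapies received before vaccination.

    ``immuno_treated`` if any prior-treatment token names an
    immune-modulating therapy (Ipi, Biot, BioCT, IL-2, IFN); otherwise
    ``naive_ct_rt`` (first-line vaccine, chemotherapy, or radiotherapy).
    Tokens are comma-separated; a trailing ``*`` footnote marker is ignored.
    """
    if not prior_treatments or not prior_treatments.strip():
        raise InputError("empty prior-treatments string")
    tokens = [
        t.strip().rstrip("*").lower()
        for t in prior_treatments.split(",")
        if t.strip()
    ]
    unknown = [t for t in tokens if t not in IMMUNO_TOKENS | NAIVE_TOKENS]
    if unknown:
        raise InputError(f"unrecognized prior-treatment token(s): {unknown}")
    if any(t in IMMUNO_TOKENS for t in tokens):
        return "immuno_treated"
    return "naive_ct_rt"
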