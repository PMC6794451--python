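"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (literal enumeration, generic numeric
optimization, rank-then-Pearson) and shares no code with the implementation
it validates.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats


def wilcoxon_exact_p_enumeration(diffs) -> float:
    """Two-sided exact signed-rank p by literally enumerating 2^n signs."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    w = min(w_pos, w_neg)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if wp <= w + 1e-12:
            count += 1
    return min(1.0, 2.0 * count / 2**n)


def similarity_sse(params, src, dst) -> float:
    s, theta, tx, ty = params
    c, si = np.cos(theta), np.sin(theta)
    r = np.array([[c, -si], [si, c]])
    mapped = src @ (s * r).T + np.array([tx, ty])
    return float(((mapped - dst) ** 2).sum())


def brute_force_similarity_fit(src, dst) -> np.ndarray:
    """Numeric minimizer of the similarity SSE: coarse grid + Nelder-Mead."""
    best = None
    for s0 in (0.5, 1.0, 2.0, 4.0):
        for th0 in np.linspace(-np.pi, np.pi, 13, endpoint=False):
            centroid_shift = dst.mean(axis=0) - src.mean(axis=0)
            x0 = [s0, th0, centroid_shift[0], centroid_shift[1]]
            res = optimize.minimize(
                similarity_sse, x0, args=(src, dst), method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
            )
            if best is None or res.fun < best.fun:
                best = res
    return best.x


def spearman_rank_pearson(x, y) -> float:
    """rho as Pearson correlation of midranks, computed independently."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
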