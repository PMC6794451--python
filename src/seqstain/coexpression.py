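"""Cross-round co-expression phenotyping.

Sequential IHC stains one marker per round on the same section; after
registration, the same physical cell appears in every round at (nearly) the
same reference-frame position. Co-expression is therefore assessed by
carrying each round's detections into the reference frame and pairing cells
across rounds by mutual nearest neighbors within a matching radius (default
6 um, about one nucleus diameter). Matched cells are counted per boolean
phenotype rule (e.g. CD8+GZMB+), and slide-level count ratios such as
GZMB:CD8 — positive GZMB cells over positive CD8 cells, regardless of
pairing — are reported alongside the stricter per-cell co-expression
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cell_quantification import CellTable
from .errors import InputError
from .registration import Transform2D

__all__ = [
    "MatchSet",
    "PhenotypeSummary",
    "transfer_coordinates",
    "match_cells",
    "phenotype_counts",
    "DEFAULT_MATCH_RADIUS_UM",
]

DEFAULT_MATCH_RADIUS_UM = 6.0


@dataclass(frozen=True)
class MatchSet:
    """One-to-one cross-round cell matching."""

    pairs: tuple[tuple[int, int, float], ...]  # (id_a, id_b, distance_px)
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]
    radius_px: float

    def __post_init__(self) -> None:
        ids_a = [p[0] for p in self.pairs]
        ids_b = [p[1] for p in self.pairs]
        if len(set(ids_a)) != len(ids_a) or len(set(ids_b)) != len(ids_b):
            raise InputError("matching must be one-to-one")
        if any(d > self.radius_px + 1e-9 for *_, d in self.pairs):
            raise InputError("match distance exceeds radius")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PhenotypeSummary:
    """Counts per phenotype rule plus named slide-level ratios.

    Ratios with a zero denominator are stored as ``None`` (explicitly
    undefined), never 0.
    """

    counts: dict[str, int]
    ratios: dict[str, float | None]
    n_matched: int
    coexpression_fraction: float | None = None
    notes: dict[str, str] = field(default_factory=dict)


def transfer_coordinates(cells: CellTable, t: Transform2D) -> CellTable:
    """Map centroids by ``t``; every measurement column is left untouched."""
    df = cells.df.copy()
    if len(df):
        xy = t.apply(df[["x", "y"]].to_numpy(dtype=float))
        df["x"] = xy[:, 0]
        df["y"] = xy[:, 1]
    return cells.with_df(df)


def match_cells(a: CellTable, b: CellTable, radius_um: float = DEFAULT_MATCH_RADIUS_UM) -> MatchSet:
    """Mutual-nearest-neighbor pairing of two cell tables in one frame.

    A pair (i, j) is kept iff j is i's nearest neighbor in b, i is j's
    nearest in a, and their distance is within the radius. Ties are broken
    deterministically by (distance, id). Symmetric: swapping the tables
    transposes the pairs.
    """
    if radius_um <= 0:
        raise InputError("matching radius must be positive")
    if abs(a.mpp - b.mpp) > 1e-12:
        raise InputError("cell tables must share mpp")
    radius_px = radius_um / a.mpp
    ids_a = a.df["id"].to_numpy(dtype=int) if len(a) else np.empty(0, dtype=int)
    ids_b = b.df["id"].to_numpy(dtype=int) if len(b) else np.empty(0, dtype=int)
    if len(a) == 0 or len(b) == 0:
        return MatchSet((), tuple(ids_a), tuple(ids_b), radius_px)

    pa = a.df[["x", "y"]].to_numpy(dtype=float)
    pb = b.df[["x", "y"]].to_numpy(dtype=float)
    tree_a, tree_b = cKDTree(pa), cKDTree(pb)
    d_ab, j_ab = tree_b.query(pa)  # nearest b for each a
    d_ba, i_ba = tree_a.query(pb)  # nearest a for each b

    candidates = []
    for i in range(len(pa)):
        j = int(j_ab[i])
        if int(i_ba[j]) == i and d_ab[i] <= radius_px:
            candidates.append((float(d_ab[i]), int(ids_a[i]), int(ids_b[j])))
    candidates.sort()  # deterministic (distance, id_a, id_b) order

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for dist, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        pairs.append((ia, ib, dist))
        used_a.add(ia)
        used_b.add(ib)
    pairs.sort(key=lambda p: p[0])
    return MatchSet(
        pairs=tuple(pairs),
        unmatched_a=tuple(int(i) for i in ids_a if i not in used_a),
        unmatched_b=tuple(int(i) for i in ids_b if i not in used_b),
        radius_px=radius_px,
    )


def phenotype_counts(
    matches: MatchSet,
    cells_a: CellTable,
    cells_b: CellTable,
    rules: dict[str, dict[str, bool]],
    ratio_defs: dict[str, tuple[str, str]] | None = None,
) -> PhenotypeSummary:
    """Count matched cells per boolean phenotype rule.

    ``rules`` maps a phenotype name to required marker states, e.g.
    ``{"CD8+GZMB+": {"CD8": True, "GZMB": True}}``; each referenced marker
    must be labeled on one of the two tables. ``ratio_defs`` maps a ratio
    name to (numerator marker, denominator marker); ratios use slide-level
    positive counts over the full tables (not only matched cells), the
    GZMB:CD8 convention. When both tables carry exactly one marker each, the
    per-cell co-expression fraction — matched pairs positive for both over
    matched pairs positive for the first table's marker — is also reported.
    """
    available: dict[str, CellTable] = {}
    for tbl in (cells_a, cells_b):
        for m in tbl.markers:
            available[m] = tbl
    for rule_name, req in rules.items():
        for m in req:
            if m not in available:
                raise InputError(f"rule {rule_name!r} references absent marker {m!r}")

    lab = {m: available[m].labels(m) for m in available}
    side = {m: ("a" if available[m] is cells_a else "b") for m in available}

    counts = {name: 0 for name in rules}
    for ia, ib, _ in matches.pairs:
        state = {m: lab[m][ia if side[m] == "a" else ib] == "positive" for m in available}
        for name, req in rules.items():
            if all(state[m] == want for m, want in req.items()):
                counts[name] += 1

    ratios: dict[str, float | None] = {}
    if ratio_defs is None and {"GZMB", "CD8"} <= set(available):
        ratio_defs = {"gzmb_cd8_ratio": ("GZMB", "CD8")}
    for name, (num_m, den_m) in (ratio_defs or {}).items():
        if num_m not in available or den_m not in available:
            raise InputError(f"ratio {name!r} references an absent marker")
        num = available[num_m].positive_count(num_m)
        den = available[den_m].positive_count(den_m)
        ratios[name] = None if den == 0 else num / den

    coexp = None
    if len(cells_a.markers) == 1 and len(cells_b.markers) == 1:
        ma, mb = cells_a.markers[0], cells_b.markers[0]
        base = both = 0
        for ia, ib, _ in matches.pairs:
            if lab[ma][ia] == "positive":
                base += 1
                if lab[mb][ib] == "positive":
                    both += 1
        coexp = (both / base) if base else None

    return PhenotypeSummary(
        counts=counts, ratios=ratios, n_matched=len(matches), coexpression_fraction=coexp
    )
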