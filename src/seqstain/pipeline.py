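"""Run configuration and the end-to-end cohort reproduction report.

:func:`reproduce_table1_stats` recomputes every headline statistic that is
derivable from the packaged study-cohort table: the exact paired Wilcoxon
tests on PDL1 percent-positivity (all assessable pairs and per treatment
group), group means +/- SEM, the count of PDL1 increases, CD8 post/pre
ratio descriptives by sampling status, and the cohort timing averages. Each
number is reported twice: ``raw`` at full precision and ``display``
formatted to the precision clinical tables print.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version

import numpy as np
import yaml

from .cell_quantification import DetectionParams
from .cohort_stats import descriptives, wilcoxon_signed_rank
from .coexpression import DEFAULT_MATCH_RADIUS_UM
from .errors import InputError
from .io_formats import PairedCohort, packaged_table1_path, read_cohort_table

__all__ = ["RunConfig", "reproduce_table1_stats"]

logger = logging.getLogger("seqstain")


@dataclass
class RunConfig:
    """Resolved run configuration; validated on load, logged on every run."""

    stains: str = "h-aec"
    detection: DetectionParams = field(default_factory=DetectionParams)
    marker_thresholds: dict[str, float] = field(default_factory=dict)
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM
    decimal: str = "comma"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.decimal not in {"comma", "point"}:
            raise InputError("decimal must be 'comma' or 'point'")
        if self.match_radius_um <= 0:
            raise InputError("match_radius_um must be positive")
        for m, t in self.marker_thresholds.items():
            if t <= 0:
                raise InputError(f"threshold for {m!r} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        det = raw.pop("detection", None)
        cfg = cls(**raw)
        if det is not None:
            cfg.detection = DetectionParams(**det)
        return cfg

    def log_resolved(self) -> None:
        try:
            ver = _pkg_version("seqstain")
        except Exception:
            ver = "unknown"
        logger.info("seqstain %s config: %s", ver, asdict(self))


def _sig4(x: float) -> str:
    return f"{x:.4g}"


def _test_entry(pre: np.ndarray, post: np.ndarray) -> dict:
    res = wilcoxon_signed_rank(pre, post)
    return {
        "n_used": res.n_used,
        "w_statistic": res.w_statistic,
        "method": res.method,
        "p_raw": res.p_two_sided,
        "p_display": f"{res.p_two_sided:.4f}",
    }


def _mean_sem_entry(values: np.ndarray) -> dict:
    d = descriptives(values)
    return {
        "n": d.n,
        "mean_raw": d.mean,
        "sem_raw": d.sem,
        "mean_display": _sig4(d.mean),
        "sem_display": _sig4(d.sem) if d.sem is not None else None,
    }


def reproduce_table1_stats(
    table_path=None, decimal: str = "comma", marker: str = "pdl1"
) -> dict:
    """Structured report of every cohort statistic the table determines.

    ``table_path`` defaults to the packaged study fixture. Raises
    :class:`InputError` when required columns (the marker's pre/post pair,
    timing, sampling, prior treatments) are absent.
    """
    if table_path is None:
        table_path = packaged_table1_path()
    cohort = read_cohort_table(table_path, decimal=decimal)
    if marker not in cohort.markers:
        raise InputError(f"cohort table lacks {marker}_pre/{marker}_post columns")
    return _build_report(cohort, marker)


def _build_report(cohort: PairedCohort, marker: str) -> dict:
    ids_all, pre_all, post_all = cohort.paired_values(marker)
    if len(ids_all) == 0:
        raise InputError(f"no complete {marker} pairs in the table")
    groups = {}
    for g in ("naive_ct_rt", "immuno_treated"):
        _, pre_g, post_g = cohort.paired_values(marker, group=g)
        groups[g] = (pre_g, post_g)

    report = {
        "marker": marker,
        "n_patients": len(cohort),
        "wilcoxon": {
            "all": _test_entry(pre_all, post_all),
            "naive_ct_rt": _test_entry(*groups["naive_ct_rt"]),
            "immuno_treated": _test_entry(*groups["immuno_treated"]),
        },
        "mean_sem": {
            "all_pre": _mean_sem_entry(pre_all),
            "all_post": _mean_sem_entry(post_all),
            "naive_ct_rt_pre": _mean_sem_entry(groups["naive_ct_rt"][0]),
            "naive_ct_rt_post": _mean_sem_entry(groups["naive_ct_rt"][1]),
            "immuno_treated_pre": _mean_sem_entry(groups["immuno_treated"][0]),
            "immuno_treated_post": _mean_sem_entry(groups["immuno_treated"][1]),
        },
        "n_pairs": len(ids_all),
        "n_increases": int(np.sum(post_all > pre_all)),
    }

    ratios_post = cohort.cd8_ratios(sampling="post_treatment")
    ratios_on_immuno = cohort.cd8_ratios(group="immuno_treated", sampling="on_treatment")
    report["cd8_ratio"] = {
        "post_treatment": _mean_sem_entry(ratios_post) if len(ratios_post) else None,
        "on_treatment_immuno": (
            _mean_sem_entry(ratios_on_immuno) if len(ratios_on_immuno) else None
        ),
    }

    surg = np.asarray(
        [p.months_surgery_to_vax for p in cohort.patients], dtype=float
    )
    surg = surg[~np.isnan(surg)]
    biopsy_post = np.asarray(
        [
            p.months_vax_to_biopsy
            for p in cohort.select(sampling="post_treatment")
        ],
        dtype=float,
    )
    biopsy_post = biopsy_post[~np.isnan(biopsy_post)]
    report["timing"] = {
        "months_surgery_to_vax": _mean_sem_entry(surg) if len(surg) else None,
        "months_vax_to_biopsy_post_treatment": (
            _mean_sem_entry(biopsy_post) if len(biopsy_post) else None
        ),
    }
    return report
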