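"""Cohort aggregation and nonparametric group comparison.

Per-subject peak/subpeak readings are collapsed into three analysis modes —
both ROIs pooled (two values per subject), peak only, or the per-subject
mean of the two — then summarized per group (mean, median, quartiles,
IQR = P75 − P25, sample SD) and compared pairwise with the two-tailed
Mann–Whitney U test at a 5% level. No multiple-testing correction is
applied; raw p-values are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import SubjectResult

logger = logging.getLogger(__name__)

ANALYSIS_MODES = ("two_rois_pooled", "peak_only", "mean_of_two")
METRICS = ("pos_percent", "pos_per_mm2")

#: Largest combined sample for which the exact (permutation) null is used
#: in the absence of ties; beyond it, tie- and continuity-corrected normal.
_EXACT_LIMIT = 16


@dataclass(frozen=True)
class GroupSummary:
    """Summary rows of one group × metric: the table machinery."""

    group: str
    metric: str
    n_subjects: int
    n_values: int
    mean: float
    median: float
    p75: float
    p25: float
    iqr: float
    sd: float


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise two-sample rank test."""

    group_a: str
    group_b: str
    metric: str
    mode: str
    u_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def collect_values(
    results: Sequence[SubjectResult], mode: str, metric: str
) -> dict[str, np.ndarray]:
    """Per-group value lists for one analysis mode and metric.

    Pooled mode contributes the peak and subpeak values of every subject
    (2 per subject); ``peak_only`` the rank-1 window; ``mean_of_two`` the
    per-subject mean. Missing pos_percent values (empty windows) are
    dropped with a logged count; subjects without a subpeak are excluded
    from modes that need one, with a warning.
    """
    if mode not in ANALYSIS_MODES:
        raise ValueError(f"unknown analysis mode {mode!r}; expected one of {ANALYSIS_MODES}")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    out: dict[str, list[float]] = {}
    n_missing = 0
    for res in results:
        grp = res.group or "all"
        vals: list[Optional[float]] = []
        if mode == "peak_only":
            vals = [getattr(res.peak, metric)]
        elif res.subpeak is None:
            logger.warning("subject %s has no subpeak window; excluded from %s", res.subject_id, mode)
            continue
        elif mode == "two_rois_pooled":
            vals = [getattr(res.peak, metric), getattr(res.subpeak, metric)]
        else:  # mean_of_two
            vals = [res.mean_of_two(metric)]
        for v in vals:
            if v is None:
                n_missing += 1
            else:
                out.setdefault(grp, []).append(float(v))
    if n_missing:
        logger.info("dropped %d missing %s values in mode %s", n_missing, metric, mode)
    return {g: np.asarray(v, dtype=float) for g, v in out.items()}


def summarize_group(
    values: Sequence[float],
    group: str = "",
    metric: str = "",
    n_subjects: Optional[int] = None,
) -> GroupSummary:
    """Mean / median / quartiles (linear interpolation) / IQR / sample SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"group {group!r}: need at least 2 values to summarize, got {arr.size}")
    p25, p75 = np.percentile(arr, [25, 75])
    return GroupSummary(
        group=group,
        metric=metric,
        n_subjects=n_subjects if n_subjects is not None else arr.size,
        n_values=arr.size,
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        p75=float(p75),
        p25=float(p25),
        iqr=float(p75 - p25),
        sd=float(arr.std(ddof=1)),
    )


def mann_whitney_u(
    values_a: Sequence[float],
    values_b: Sequence[float],
    group_a: str = "A",
    group_b: str = "B",
    metric: str = "",
    mode: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-tailed Mann–Whitney U test.

    U is computed from midranks. The p-value uses the exact permutation
    null when the combined sample is small (≤ 16) and tie-free, otherwise
    the tie-corrected normal approximation with continuity correction.
    Identical samples yield p = 1 rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(group_a, group_b, metric, mode, a.size * b.size / 2.0, 1.0, alpha)
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= _EXACT_LIMIT and not has_ties:
        method = "exact"
        use_continuity = False
    else:
        method = "asymptotic"
        use_continuity = True
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=use_continuity
    )
    return ComparisonResult(
        group_a=group_a,
        group_b=group_b,
        metric=metric,
        mode=mode,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alpha=alpha,
    )


_COMPARISON_PAIRS = (("HV", "EoE"), ("GERD", "HV"), ("EoE", "GERD"))


def build_comparison_table(
    results: Sequence[SubjectResult],
    alpha: float = 0.05,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full table machinery: summaries + pairwise tests per mode × metric.

    With the default pairs the three groups HV, GERD and EoE must all be
    present; the comparisons are HV vs EoE, GERD vs HV and EoE vs GERD.
    Returns (summaries, comparisons) DataFrames.
    """
    groups_present = {r.group for r in results}
    if pairs is None:
        pairs = _COMPARISON_PAIRS
        missing = {g for p in pairs for g in p} - groups_present
        if missing:
            raise ValueError(f"missing groups in results: {sorted(missing)}")
    n_subj = {g: sum(1 for r in results if r.group == g) for g in groups_present}

    sum_rows, cmp_rows = [], []
    for mode in ANALYSIS_MODES:
        for metric in METRICS:
            per_group = collect_values(results, mode, metric)
            for g, vals in per_group.items():
                s = summarize_group(vals, group=g, metric=metric, n_subjects=n_subj[g])
                sum_rows.append(
                    {
                        "mode": mode,
                        "metric": metric,
                        "group": g,
                        "n_subjects": s.n_subjects,
                        "n_values": s.n_values,
                        "mean": s.mean,
                        "median": s.median,
                        "p75": s.p75,
                        "p25": s.p25,
                        "iqr": s.iqr,
                        "sd": s.sd,
                    }
                )
            for ga, gb in pairs:
                if ga not in per_group or gb not in per_group:
                    continue
                c = mann_whitney_u(
                    per_group[ga], per_group[gb], ga, gb, metric=metric, mode=mode, alpha=alpha
                )
                cmp_rows.append(
                    {
                        "mode": mode,
                        "metric": metric,
                        "group_a": ga,
                        "group_b": gb,
                        "u_statistic": c.u_statistic,
                        "p_value": c.p_value,
                        "alpha": alpha,
                        "significant": c.significant,
                    }
                )
    return pd.DataFrame(sum_rows), pd.DataFrame(cmp_rows)
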