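"""Cohort statistics: severity filtering, group comparisons, FDR control.

Group labels: Ctrl (healthy controls), DEP (depressed, no suicide attempt),
SA (suicide attempters); MDD denotes the merged patient group DEP + SA.

Severity on the two clinician rating scales (MADRS and IDS-C30):
low 7 ≤ MADRS ≤ 19, moderate 20 ≤ MADRS ≤ 34, severe MADRS ≥ 35 (IDS-C30
bins 12–23 / 24–36 / ≥ 37 used when MADRS is missing).  The analysis set
drops low-severity patients, keeping those with MADRS ≥ 20 or IDS-C30 ≥ 24.

Each pairwise comparison reports both a Wilcoxon rank-sum test and Welch's
t-test per feature, with Benjamini–Hochberg adjustment across the feature
family within that comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SeverityClass",
    "classify_severity",
    "filter_analysis_set",
    "retained_after_low_severity_exclusion",
    "wilcoxon_rank_sum",
    "welch_t",
    "welch_t_from_stats",
    "bh_adjust",
    "site_correlation_matrix",
    "mean_variation",
    "qpcr_relative_expression",
    "differential_table",
    "COMPARISONS",
]

#: group memberships per named comparison (second group is the case group)
COMPARISONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "Ctrl_vs_MDD": (("Ctrl",), ("DEP", "SA")),
    "Ctrl_vs_DEP": (("Ctrl",), ("DEP",)),
    "Ctrl_vs_SA": (("Ctrl",), ("SA",)),
    "DEP_vs_SA": (("DEP",), ("SA",)),
}


class SeverityClass(str, Enum):
    NONE = "none"
    LOW = "low"
    MODERATE = "moderate"
    SEVERE = "severe"


def classify_severity(
    group: str, madrs: float | None = None, idsc30: float | None = None
) -> SeverityClass:
    """Bin a subject's depression severity.

    MADRS takes precedence; IDS-C30 is used only when MADRS is missing
    (the two scales' "and/or" definition is contradictory for discordant
    subjects, and a deterministic precedence resolves it).  Controls are
    always `none`.
    """
    if group == "Ctrl":
        return SeverityClass.NONE
    if madrs is not None and not (isinstance(madrs, float) and np.isnan(madrs)):
        score, bins = madrs, (7, 20, 35)
    elif idsc30 is not None and not (isinstance(idsc30, float) and np.isnan(idsc30)):
        score, bins = idsc30, (12, 24, 37)
    else:
        raise ValueError("patient record with both severity scores missing")
    if score >= bins[2]:
        return SeverityClass.SEVERE
    if score >= bins[1]:
        return SeverityClass.MODERATE
    if score >= bins[0]:
        return SeverityClass.LOW
    return SeverityClass.LOW  # sub-threshold patient scores bin with low severity


def filter_analysis_set(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop low-severity patients; keep all controls.

    Patients are retained when MADRS ≥ 20 or IDS-C30 ≥ 24 (the moderate
    boundary).  Returns the retained records and per-group excluded counts.
    """
    required = {"group", "MADRS", "IDSC30"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    is_ctrl = records["group"] == "Ctrl"
    keep_patient = (records["MADRS"] >= 20) | (records["IDSC30"] >= 24)
    keep = is_ctrl | keep_patient
    excluded = (
        records.loc[~keep, "group"].value_counts().to_dict()
        if (~keep).any()
        else {}
    )
    return records.loc[keep].copy(), {g: int(n) for g, n in excluded.items()}


def retained_after_low_severity_exclusion(severity_counts: Mapping[str, int]) -> int:
    """Retained group size given a printed severity breakdown.

    Only the low-vs-rest boundary matters for the analysis set: everything
    except the low-severity bin is retained.
    """
    return sum(int(n) for k, n in severity_counts.items() if k != "low")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration for small untied samples, tie-corrected normal
    approximation otherwise.  Constant pooled data yields p = 1 with a
    warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled data; rank-sum test is uninformative")
        return float(len(x) * len(y) / 2.0), 1.0
    small = max(len(x), len(y)) <= 25
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if small and not has_ties else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t_from_stats(
    mean_x: float, sd_x: float, n_x: int, mean_y: float, sd_y: float, n_y: int
) -> tuple[float, float, float]:
    """Welch's t from summary statistics; returns (t, Satterthwaite df, p)."""
    if min(n_x, n_y) < 2:
        raise ValueError("need n >= 2 per group")
    if sd_x < 0 or sd_y < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd_x == 0 and sd_y == 0:
        # degenerate: no within-group variability
        if mean_x == mean_y:
            return 0.0, float(n_x + n_y - 2), 1.0
        return float(np.sign(mean_x - mean_y) * np.inf), float(n_x + n_y - 2), 0.0
    vx, vy = sd_x**2 / n_x, sd_y**2 / n_y
    df = (vx + vy) ** 2 / (vx**2 / (n_x - 1) + vy**2 / (n_y - 1))
    res = sps.ttest_ind_from_stats(mean_x, sd_x, n_x, mean_y, sd_y, n_y, equal_var=False)
    return float(res.statistic), float(df), float(res.pvalue)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t-test on raw data; returns (t, Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(len(x), len(y)) < 2:
        raise ValueError("need n >= 2 per group")
    return welch_t_from_stats(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def site_correlation_matrix(
    records: pd.DataFrame, features: Sequence[str], by_group: bool = True
) -> pd.DataFrame:
    """Pearson correlations (with p-values) between editing features.

    Returns a long-format frame: group, feature_i, feature_j, r, p.
    Zero-variance features give missing correlations rather than errors.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 subjects")
    groups = records.groupby("group") if by_group else [("all", records)]
    rows = []
    for gname, gdf in groups:
        for i, fi in enumerate(features):
            for fj in features[i:]:
                xi, xj = gdf[fi].to_numpy(float), gdf[fj].to_numpy(float)
                if np.std(xi) == 0 or np.std(xj) == 0:
                    r, p = (1.0, 0.0) if fi == fj else (np.nan, np.nan)
                elif fi == fj:
                    r, p = 1.0, 0.0
                else:
                    r, p = sps.pearsonr(xi, xj)
                rows.append(
                    {"group": gname, "feature_i": fi, "feature_j": fj,
                     "r": float(r) if r == r else np.nan, "p": p}
                )
    return pd.DataFrame(rows)


def mean_variation(control_mean: float, case_mean: float) -> float | None:
    """Percent variation of a case-group mean relative to the control mean:
    100 × (case − control) / control; undefined (None) for control = 0."""
    if control_mean == 0:
        return None
    return 100.0 * (case_mean - control_mean) / control_mean


HOUSEKEEPING_GENES = ("HPRT1", "GAPDH", "TBP", "PGK1")


def qpcr_relative_expression(
    quantities: Mapping[str, float], target: str,
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
) -> float:
    """Absolute-quantification qPCR value normalised by the geometric mean of
    the housekeeping genes."""
    hk = []
    for gene in housekeeping:
        q = quantities[gene]
        if q <= 0:
            raise ValueError(f"housekeeping quantity for {gene} must be > 0")
        hk.append(q)
    return float(quantities[target] / sps.gmean(hk))


@dataclass
class DifferentialResult:
    feature: str
    comparison: str
    mean_ref: float
    sem_ref: float
    mean_case: float
    sem_case: float
    w_statistic: float
    p_wilcoxon: float
    t_statistic: float
    df: float
    p_welch: float
    p_wilcoxon_adj: float = np.nan
    p_welch_adj: float = np.nan
    significant: bool = False


def differential_table(
    records: pd.DataFrame,
    features: Sequence[str],
    comparisons: Iterable[str] = COMPARISONS,
) -> pd.DataFrame:
    """Per-feature group comparisons with BH adjustment within each comparison.

    For every comparison both tests are run per feature; BH is applied to
    each test's p-values across the feature family of that comparison.  The
    significance flag uses the adjusted rank-sum p at 0.05 (the rank-sum test
    makes no normality assumption on the skewed minor-pattern proportions).
    Means are reported ± SEM (SD/√n).
    """
    results: list[DifferentialResult] = []
    for comp in comparisons:
        if comp not in COMPARISONS:
            raise ValueError(f"unknown comparison {comp!r}")
        ref_groups, case_groups = COMPARISONS[comp]
        ref = records[records["group"].isin(ref_groups)]
        case = records[records["group"].isin(case_groups)]
        if len(ref) < 2 or len(case) < 2:
            raise ValueError(f"comparison {comp}: a group is absent or too small")
        block: list[DifferentialResult] = []
        for feat in features:
            x = ref[feat].to_numpy(float)
            y = case[feat].to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w, p_w = wilcoxon_rank_sum(x, y)
                t, df, p_t = welch_t(x, y)
            block.append(
                DifferentialResult(
                    feature=feat,
                    comparison=comp,
                    mean_ref=float(x.mean()),
                    sem_ref=float(x.std(ddof=1) / np.sqrt(len(x))),
                    mean_case=float(y.mean()),
                    sem_case=float(y.std(ddof=1) / np.sqrt(len(y))),
                    w_statistic=w,
                    p_wilcoxon=p_w,
                    t_statistic=t,
                    df=df,
                    p_welch=p_t,
                )
            )
        adj_w = bh_adjust([r.p_wilcoxon for r in block])
        adj_t = bh_adjust([r.p_welch for r in block])
        for r, aw, at in zip(block, adj_w, adj_t):
            r.p_wilcoxon_adj = float(aw)
            r.p_welch_adj = float(at)
            r.significant = aw < 0.05
        results.extend(block)
    return pd.DataFrame([vars(r) for r in results])
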