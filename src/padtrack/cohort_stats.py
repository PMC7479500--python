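"""Demographic and clinical comparison machinery.

Kruskal–Wallis tests with Dunn's pairwise follow-up for skewed continuous
variables, chi-squared tests for categorical tables (with Yates continuity
correction on 2x2 tables, which reproduces the attrition comparisons),
per-group attrition percentages, and subclinical depression-symptom rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .config import GROUPS


@dataclass(frozen=True)
class GroupComparisonResult:
    variable: str
    test: str  # kruskal_wallis | chi_squared | chi_squared_yates
    statistic: float
    df: int
    p: float
    pairwise: pd.DataFrame | None = None

    def __post_init__(self):
        if self.statistic < 0 or not 0 < self.p <= 1:
            raise ValueError(f"invalid test result for {self.variable}: {self.statistic}, {self.p}")


def kruskal_wallis(groups: list[np.ndarray], variable: str = "") -> GroupComparisonResult:
    """Rank-based H test across k groups with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupComparisonResult(variable, "kruskal_wallis", 0.0, len(groups) - 1, 1.0)
    h, p = stats.kruskal(*groups)
    return GroupComparisonResult(variable, "kruskal_wallis", float(h), len(groups) - 1, float(p))


def dunn_pairwise(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's z tests on pooled ranks with tie correction, unadjusted p.

    Returns one row per unordered pair; the z sign follows (first group
    mean rank) minus (second group mean rank).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group passed to Dunn's test")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append((labels[i], labels[j], float(z), float(2 * stats.norm.sf(abs(z)))))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])


def chi_square_yates(table: np.ndarray, variable: str = "") -> GroupComparisonResult:
    """Yates continuity-corrected chi-square on a 2x2 count table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise ValueError("counts must be non-negative numbers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=True)
    return GroupComparisonResult(variable, "chi_squared_yates", float(chi2), int(df), float(p))


def chi_square(table: np.ndarray, variable: str = "") -> GroupComparisonResult:
    """Pearson chi-square (no correction) for r x c tables."""
    table = np.asarray(table)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparisonResult(variable, "chi_squared", float(chi2), int(df), float(p))


@dataclass(frozen=True)
class AttritionReport:
    """Per-group baseline/follow-up ns, attrition percents, pairwise tests."""

    baseline_n: dict[str, int]
    followup_n: dict[str, int]
    attrition_percent: dict[str, float] = field(init=False)
    pairwise: pd.DataFrame | None = None

    def __post_init__(self):
        pct = {
            g: 100.0 * (self.baseline_n[g] - self.followup_n.get(g, 0)) / self.baseline_n[g]
            for g in self.baseline_n
        }
        object.__setattr__(self, "attrition_percent", pct)

    def to_dict(self) -> dict:
        out = {
            "baseline_n": self.baseline_n,
            "followup_n": self.followup_n,
            "attrition_percent": self.attrition_percent,
        }
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        return out


def attrition_report(cohort: Cohort) -> AttritionReport:
    """Attrition percentages and the three pairwise Yates chi-squares.

    Each 2x2 table is (group x retained/lost), so rows sum to the two
    groups' baseline ns.
    """
    base = cohort.group_sizes("t1")
    fu = cohort.group_sizes("t2")
    present = [g for g in GROUPS if g in base]
    rows = []
    for a, b in combinations(present, 2):
        table = np.array(
            [
                [fu.get(a, 0), base[a] - fu.get(a, 0)],
                [fu.get(b, 0), base[b] - fu.get(b, 0)],
            ]
        )
        if np.any(table.sum(axis=0) == 0):
            # all-retained (or all-lost) in both groups: no association testable
            rows.append((a, b, 0.0, 1.0))
            continue
        res = chi_square_yates(table, f"attrition {a} vs {b}")
        rows.append((a, b, res.statistic, res.p))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "chi2", "p"])
    return AttritionReport(base, fu, pairwise=pairwise)


def subclinical_rate(hrsd_scores, threshold: int = 7) -> float:
    """Proportion of scores strictly above the subclinical cut-off."""
    scores = np.asarray(hrsd_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no HRSD scores supplied")
    if np.any(scores < 0):
        raise ValueError("HRSD scores must be non-negative")
    return float(np.mean(scores > threshold))


def demographics_table(cohort: Cohort) -> pd.DataFrame:
    """Table-1-style summary: per-group ns, ages, sex, HRSD with tests."""
    df = cohort.table
    present = [g for g in GROUPS if g in set(df["group"])]
    by = {g: df[df["group"] == g] for g in present}
    rows = []

    def med_iqr(vals):
        vals = vals.dropna()
        if vals.empty:
            return "-"
        q1, q3 = np.percentile(vals, [25, 75])
        return f"{np.median(vals):.1f} ({q3 - q1:.1f})"

    rows.append(["n, timepoint 1", *[str(len(by[g])) for g in present], ""])
    rows.append(
        ["n, timepoint 2", *[str(int(by[g]["has_followup"].sum())) for g in present], ""]
    )
    for var, col in (("Age, timepoint 1", "age_t1"), ("Age, timepoint 2", "age_t2"),
                     ("HRSD, timepoint 1", "hrsd_t1"), ("HRSD, timepoint 2", "hrsd_t2")):
        vals = [by[g][col].dropna().to_numpy() for g in present]
        res = kruskal_wallis(vals, var)
        rows.append([var, *[med_iqr(by[g][col]) for g in present], f"{res.p:.3f}"])
    sex_table = np.array(
        [[int((by[g]["sex"] == s).sum()) for g in present] for s in (0, 1)]
    )
    res = chi_square(sex_table, "sex")
    rows.append(
        ["Female, n", *[str(int((by[g]['sex'] == 1).sum())) for g in present], f"{res.p:.3f}"]
    )
    return pd.DataFrame(rows, columns=["variable", *present, "p"])
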