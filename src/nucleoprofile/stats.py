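"""Cross-condition statistics: Pearson correlations, one-way ANOVA with
Tukey HSD post-hoc tests, and per-condition summary tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "correlate",
    "compare_groups",
    "summarize_conditions",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    variable_x: str
    variable_y: str
    r: float
    r_squared: float
    n: int


@dataclass
class GroupComparison:
    variable: str
    anova_p: float
    anova_f: float
    tukey: pd.DataFrame  # columns: group1, group2, p_adj, significant
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.anova_p < self.alpha


def correlate(x, y, name_x: str = "x", name_y: str = "y") -> CorrelationResult:
    """Pearson r and r-squared for a 2-D scatterplot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(sps.pearsonr(x, y).statistic)
    return CorrelationResult(name_x, name_y, r, r * r, int(x.size))


def compare_groups(
    table: pd.DataFrame, variable: str, grouping: str = "condition", alpha: float = ALPHA
) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD pairwise comparisons across groups."""
    df = table[[grouping, variable]].dropna()
    groups = [g[variable].to_numpy(dtype=float) for _, g in df.groupby(grouping, sort=True)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError(f"degenerate zero-variance groups for {variable!r}")
    f_stat, p = sps.f_oneway(*groups)
    if f_stat < 0:  # catastrophic cancellation when groups are identical
        f_stat, p = 0.0, 1.0
    tk = pairwise_tukeyhsd(
        df[variable].to_numpy(dtype=float), df[grouping].astype(str).to_numpy(), alpha=alpha
    )
    tukey = pd.DataFrame(
        {
            "group1": tk.groupsunique[tk._multicomp.pairindices[0]],
            "group2": tk.groupsunique[tk._multicomp.pairindices[1]],
            "p_adj": tk.pvalues,
            "significant": tk.reject,
        }
    )
    return GroupComparison(
        variable=variable, anova_p=float(p), anova_f=float(f_stat), tukey=tukey, alpha=alpha
    )


_SUMMARY_VARS = [
    "foci_count",
    "mean_focus_area_px",
    "coverage_percent",
    "hc_percent",
    "nucleus_area_px",
]


def summarize_conditions(per_nucleus: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per condition for the headline per-nucleus variables.

    Every number here is recomputable from the per-nucleus table alone.
    """
    rows = []
    for cond, grp in per_nucleus.groupby("condition", sort=True):
        row: dict = {"condition": cond, "n_nuclei": len(grp)}
        row["labeling_index_percent"] = 100.0 * grp["labeled"].mean()
        for var in _SUMMARY_VARS:
            if var not in grp:
                continue
            row[f"{var}_mean"] = float(grp[var].mean())
            row[f"{var}_sd"] = float(grp[var].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
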