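"""Longitudinal clinical-parameter testing.

For each clinical parameter measured at the three study timepoints the
engine (i) mean-imputes missing values, (ii) gates on per-timepoint
Shapiro–Wilk normality, (iii) runs a repeated-measures ANOVA (parametric
branch) or a Friedman test (nonparametric branch) across T1/T2/T3, and
(iv) when the omnibus test is significant, follows up with paired t or
Wilcoxon signed-rank tests for the three timepoint pairs, Bonferroni-
adjusted within the parameter (m = 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TIMEPOINTS

__all__ = [
    "LongitudinalTestResult",
    "ControlComparison",
    "impute_missing",
    "test_parameter",
    "test_all_parameters",
    "compare_to_controls",
]

PAIRS = (("T1", "T2"), ("T1", "T3"), ("T2", "T3"))


@dataclass
class LongitudinalTestResult:
    parameter: str
    n: int                         # complete triplets used
    omnibus_test: str              # 'rm_anova' | 'friedman'
    omnibus_statistic: float
    omnibus_p: float
    posthoc_test: str | None       # 'paired_t' | 'wilcoxon' | None
    pairwise: pd.DataFrame | None  # pair, p_raw, p_adj; None when omnibus n.s.


@dataclass
class ControlComparison:
    test: str                      # 'welch_t' | 'mann_whitney'
    statistic: float
    p_value: float
    note: str | None = None


def impute_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values by the parameter's mean over all observed values.

    The mean pools patients and timepoints, so imputation leaves each
    parameter's overall mean unchanged.  A parameter with no observed value
    at all is an error.
    """
    out = table.copy()
    for param, rows in out.groupby("parameter", sort=False):
        observed = rows["value"].dropna()
        if observed.empty:
            raise ValueError(f"parameter {param!r} has no observed values")
        fill = observed.mean()
        idx = rows.index[rows["value"].isna()]
        out.loc[idx, "value"] = fill
    return out


def _triplets(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    rows = table[table["parameter"] == parameter]
    if rows.empty:
        raise KeyError(f"parameter {parameter!r} not in table")
    wide = rows.pivot(index="patient_id", columns="timepoint", values="value")
    wide = wide.reindex(columns=list(TIMEPOINTS)).dropna(how="any")
    if len(wide) < 3:
        raise ValueError(
            f"parameter {parameter!r}: {len(wide)} complete triplets < 3"
        )
    return wide


def _is_normalish(column: np.ndarray, normality_alpha: float) -> bool:
    if np.ptp(column) == 0:
        return False
    _, p = stats.shapiro(column)
    return p >= normality_alpha


def _rm_anova(data: np.ndarray) -> tuple[float, float]:
    """One-way within-subject ANOVA on an n-subjects × k-conditions array."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((data - grand) ** 2).sum() - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return (0.0, 1.0) if ms_cond <= 0 else (np.inf, 0.0)
    f = ms_cond / ms_err
    return float(f), float(stats.f.sf(f, df_cond, df_err))


def _paired_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    if test == "paired_t":
        if np.ptp(diff) == 0:  # constant nonzero shift: t undefined, treat as extreme
            return 0.0
        return float(stats.ttest_rel(a, b).pvalue)
    # Wilcoxon signed-rank: zeros dropped (Wilcoxon's original treatment),
    # exact null for small n without ties, normal approximation otherwise.
    return float(stats.wilcoxon(a, b, zero_method="wilcox", method="auto").pvalue)


def bonferroni(p: float, m: int = 3) -> float:
    return min(1.0, m * p)


def test_parameter(
    table: pd.DataFrame,
    parameter: str,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> LongitudinalTestResult:
    """Omnibus-plus-posthoc longitudinal test of one clinical parameter.

    The parametric branch (repeated-measures ANOVA, paired t post hoc) is
    taken only when every timepoint passes Shapiro–Wilk at
    ``normality_alpha``; otherwise Friedman with Wilcoxon post hoc.  Post hoc
    pairs are tested only when the omnibus p is below ``alpha`` and are
    Bonferroni-adjusted over the three comparisons.
    """
    wide = _triplets(table, parameter)
    data = wide.to_numpy(dtype=float)
    normal = all(_is_normalish(data[:, j], normality_alpha) for j in range(data.shape[1]))
    if normal:
        omnibus_test, posthoc = "rm_anova", "paired_t"
        statistic, p = _rm_anova(data)
    else:
        omnibus_test, posthoc = "friedman", "wilcoxon"
        if np.ptp(data, axis=1).max() == 0:  # every patient flat across timepoints
            statistic, p = 0.0, 1.0
        else:
            statistic, p = stats.friedmanchisquare(*(data[:, j] for j in range(data.shape[1])))
            statistic, p = float(statistic), float(p)
    pairwise = None
    if p < alpha:
        rows = []
        for t_a, t_b in PAIRS:
            raw = _paired_p(wide[t_a].to_numpy(), wide[t_b].to_numpy(), posthoc)
            rows.append(
                dict(pair=f"{t_a}-{t_b}", p_raw=raw, p_adj=bonferroni(raw, len(PAIRS)))
            )
        pairwise = pd.DataFrame(rows).set_index("pair")
    return LongitudinalTestResult(
        parameter=parameter,
        n=len(wide),
        omnibus_test=omnibus_test,
        omnibus_statistic=statistic,
        omnibus_p=p,
        posthoc_test=posthoc if pairwise is not None else None,
        pairwise=pairwise,
    )


def test_all_parameters(
    table: pd.DataFrame, alpha: float = 0.05, normality_alpha: float = 0.05
) -> pd.DataFrame:
    """Flat Table-1-style report over every parameter in a long table."""
    rows = []
    for parameter in table["parameter"].unique():
        res = test_parameter(table, parameter, alpha=alpha, normality_alpha=normality_alpha)
        row = dict(
            parameter=parameter,
            n=res.n,
            omnibus_test=res.omnibus_test,
            omnibus_p=res.omnibus_p,
        )
        for pair in [f"{a}-{b}" for a, b in PAIRS]:
            if res.pairwise is not None and pair in res.pairwise.index:
                row[f"p_{pair}"] = res.pairwise.loc[pair, "p_raw"]
                row[f"p_adj_{pair}"] = res.pairwise.loc[pair, "p_adj"]
            else:
                row[f"p_{pair}"] = np.nan
                row[f"p_adj_{pair}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def compare_to_controls(
    values, control_values, normality_alpha: float = 0.05
) -> ControlComparison:
    """Study-vs-controls comparison of one parameter at one timepoint.

    Welch's t when both groups pass Shapiro–Wilk, two-sided Mann–Whitney U
    otherwise.  Two identical constant groups are reported as p = 1 with a
    note rather than a degenerate test statistic.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both groups need >= 3 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return ControlComparison(
            test="mann_whitney", statistic=len(x) * len(y) / 2, p_value=1.0,
            note="both groups constant and identical",
        )
    if _is_normalish(x, normality_alpha) and _is_normalish(y, normality_alpha):
        res = stats.ttest_ind(x, y, equal_var=False)
        return ControlComparison(test="welch_t", statistic=float(res.statistic),
                                 p_value=float(res.pvalue))
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return ControlComparison(test="mann_whitney", statistic=float(res.statistic),
                             p_value=float(res.pvalue))
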