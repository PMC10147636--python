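"""Scalar group statistics: Welch tests, Hedges' g, mixed ANOVA, correlations.

These are the desk statistics used around the network analyses: two-tailed
Welch t-tests (from raw samples or printed summary statistics), paired t-tests
on difference scores, Hedges' g standardized mean differences with the
small-sample correction, the 2x2 group-by-time mixed ANOVA interaction, the
Holm-Bonferroni step-down adjustment, and Pearson correlation reports with
per-family Holm correction and pairwise deletion of missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SummaryStats",
    "TestResult",
    "welch_t",
    "welch_t_from_stats",
    "paired_t",
    "hedges_g",
    "mixed_anova",
    "holm_adjust",
    "correlate",
]


@dataclass(frozen=True)
class SummaryStats:
    """Printed summary of one group: mean, SD and n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class TestResult:
    statistic: float
    df: float | tuple
    p: float
    g: float | None = None
    note: str = ""


def _hedges_j(df: float) -> float:
    # small-sample correction factor; J < 1, -> 1 as df grows
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(a, b) -> float:
    """Two-sample Hedges' g: J * (mean_a - mean_b) / pooled sd."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    if sp == 0:
        raise ValueError("zero pooled standard deviation")
    return float(_hedges_j(n1 + n2 - 2) * (a.mean() - b.mean()) / sp)


def welch_t_from_stats(a: SummaryStats, b: SummaryStats) -> TestResult:
    """Two-tailed Welch t-test from summary statistics (Welch-Satterthwaite df)."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if va + vb == 0:
        return TestResult(statistic=0.0, df=float(a.n + b.n - 2), p=1.0, note="both groups have zero variance")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    sp = np.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2))
    g = None if sp == 0 else float(_hedges_j(a.n + b.n - 2) * (a.mean - b.mean) / sp)
    return TestResult(statistic=float(t), df=float(df), p=float(p), g=g)


def welch_t(a=None, b=None, *, summary_a: SummaryStats | None = None, summary_b: SummaryStats | None = None) -> TestResult:
    """Two-tailed Welch t-test from raw samples or from summary statistics.

    Raw data are reduced to their summary statistics first, so both routes
    agree to machine precision.
    """
    if summary_a is None:
        a = np.asarray(a, dtype=float)
        summary_a = SummaryStats(mean=float(a.mean()), sd=float(a.std(ddof=1)), n=len(a))
    if summary_b is None:
        b = np.asarray(b, dtype=float)
        summary_b = SummaryStats(mean=float(b.mean()), sd=float(b.std(ddof=1)), n=len(b))
    return welch_t_from_stats(summary_a, summary_b)


def paired_t(values_t1, values_t2) -> TestResult:
    """Paired t-test on difference scores (t2 - t1), df = n - 1.

    The effect size is the paired Hedges' g: mean(diff)/sd(diff) with the
    small-sample correction at df = n - 1.
    """
    x1 = np.asarray(values_t1, dtype=float)
    x2 = np.asarray(values_t2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    n = len(x1)
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = x2 - x1
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult(statistic=0.0, df=float(n - 1), p=1.0, g=0.0, note="zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    g = _hedges_j(n - 1) * d.mean() / sd
    return TestResult(statistic=float(t), df=float(n - 1), p=float(p), g=float(g))


def mixed_anova(data: pd.DataFrame, dv: str = "value", subject: str = "subject_id", between: str = "group", within: str = "time_point") -> TestResult:
    """Group-by-time interaction of the 2x2 mixed (split-plot) ANOVA.

    Incomplete subjects (missing a time point) are dropped listwise, with the
    count recorded in the result note. For the two-level design the
    interaction F has (1, N - 2) degrees of freedom and equals the squared
    pooled two-sample t on change scores.
    """
    import pingouin as pg  # deferred: heavy import

    wide = data.pivot_table(index=[subject, between], columns=within, values=dv)
    n_total = wide.shape[0]
    complete = wide.dropna()
    dropped = n_total - complete.shape[0]
    if complete.index.get_level_values(between).nunique() != 2 or complete.shape[1] != 2:
        raise ValueError("mixed_anova supports exactly two groups and two time points")
    long = complete.reset_index().melt(id_vars=[subject, between], var_name=within, value_name=dv)
    aov = pg.mixed_anova(data=long, dv=dv, within=within, subject=subject, between=between)
    row = aov[aov["Source"] == "Interaction"].iloc[0]
    note = f"{dropped} incomplete subject(s) dropped" if dropped else ""
    return TestResult(
        statistic=float(row["F"]),
        df=(float(row["DF1"]), float(row["DF2"])),
        p=float(row["p_unc"]),
        note=note,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (original order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def correlate(parameters: pd.DataFrame, metrics: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pearson correlations of each metric with each clinical parameter.

    Both inputs are subject-indexed DataFrames; missing values are deleted
    pairwise, with the effective n reported. The Holm family is the set of
    parameters within one metric.
    """
    rows = []
    for metric in metrics.columns:
        fam = []
        for param in parameters.columns:
            joined = pd.concat([metrics[metric], parameters[param]], axis=1, join="inner").dropna()
            n = len(joined)
            if n < min_n:
                raise ValueError(f"fewer than {min_n} paired observations for {metric} vs {param}")
            x, yv = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
            if np.std(x) == 0 or np.std(yv) == 0:
                raise ValueError(f"constant vector in {metric} vs {param}")
            r, p = sps.pearsonr(x, yv)
            fam.append((metric, param, n, float(r), float(p)))
        adj = holm_adjust([f[4] for f in fam])
        rows.extend((m, pa, n, r, p, float(ph)) for (m, pa, n, r, p), ph in zip(fam, adj))
    return pd.DataFrame(rows, columns=["metric", "parameter", "n", "r", "p", "p_holm"])
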