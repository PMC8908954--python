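"""Statistical comparisons between GPS-derived and dead-reckoned metrics.

Paired t-tests compare the two positioning methods on the same
badger-nights; Welch's unequal-variance t-tests compare the two animals;
and a one-way linear model with Tukey HSD post hoc contrasts compares time
spent near the four landscape feature classes.  Proportions of time near
buildings and roads are log10(x + 1)-transformed before modelling because
many nights contain zeros.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "paired_comparison",
    "welch_comparison",
    "log10_plus_one",
    "landuse_model",
]


@dataclass
class TestResult:
    """A test statistic with degrees of freedom, p-value and effect summary."""

    statistic: float
    df: float
    p_value: float
    effect: dict = field(default_factory=dict)
    test: str = ""
    flag: Optional[str] = None

    def __str__(self) -> str:
        return (f"{self.test}: stat={self.statistic:.3f}, df={self.df:.2f}, "
                f"p={self.p_value:.4g}")


def _summary(x: np.ndarray) -> dict:
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))
            if len(x) > 1 else 0.0, "n": int(len(x))}


def paired_comparison(x, y) -> TestResult:
    """Classical paired t-test on ``x - y`` with ``df = n - 1``.

    Zero-variance non-zero differences (a constant offset between the
    series) give an infinite statistic, reported with ``p = 0`` and a
    ``zero_variance`` flag rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing pairs are not allowed in a paired test")
    d = x - y
    effect = {"x": _summary(x), "y": _summary(y), "diff": _summary(d)}
    sd = np.std(d, ddof=1)
    if sd == 0.0:
        if np.mean(d) == 0.0:
            return TestResult(0.0, n - 1, 1.0, effect, "paired t")
        stat = float(np.inf) * float(np.sign(np.mean(d)))
        return TestResult(stat, n - 1, 0.0, effect, "paired t",
                          flag="zero_variance")
    res = sps.ttest_rel(x, y)
    return TestResult(float(res.statistic), float(n - 1), float(res.pvalue),
                      effect, "paired t")


def welch_comparison(a, b) -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    effect = {"a": _summary(a), "b": _summary(b)}
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      effect, "welch t")


def log10_plus_one(values) -> np.ndarray:
    """``log10(v + 1)`` elementwise; zeros map to zero.  Negative input is
    an error (proportions and times are non-negative)."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("log10(x + 1) transform requires non-negative input")
    return np.log10(values + 1.0)


def _pooled_t_p(a: np.ndarray, b: np.ndarray) -> float:
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def landuse_model(
    table: pd.DataFrame,
    source: Optional[str] = None,
    value_col: str = "value",
    class_col: str = "feature_class",
    transform_classes: tuple = ("building", "road"),
) -> tuple[TestResult, pd.DataFrame]:
    """One-way linear model of time near features, with Tukey HSD post hoc.

    ``table`` is long-form with one row per (night, feature class)
    observation.  Values for the classes named in ``transform_classes`` are
    log10(x + 1)-transformed first.  Returns the overall F test and a table
    of all pairwise contrasts with Tukey-adjusted and raw (pooled-t)
    p-values.
    """
    df = table.copy()
    if source is not None and "source" in df.columns:
        df = df[df["source"] == source]
    if df.groupby(class_col)[value_col].count().min() < 2:
        raise ValueError("need at least 2 observations per feature class")
    df[value_col] = df[value_col].astype(float)
    mask = df[class_col].isin(transform_classes)
    df.loc[mask, value_col] = log10_plus_one(df.loc[mask, value_col])

    groups = {k: g[value_col].to_numpy() for k, g in df.groupby(class_col)}
    names = sorted(groups)
    k = len(names)
    n = len(df)
    grand = df[value_col].mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df1, df2 = k - 1, n - k
    effect = {name: _summary(groups[name]) for name in names}

    # Tolerance absorbs float residue from the grand-mean subtraction when
    # every observation is identical.
    tol = 1e-20 * n * max(1.0, float(grand) ** 2)
    if ss_within <= tol and ss_between <= tol:
        overall = TestResult(0.0, float(df1), 1.0, effect, "one-way F",
                             flag="zero_variance")
        pairs = pd.DataFrame(
            [{"group1": a, "group2": b, "meandiff": 0.0,
              "p_adj": 1.0, "p_raw": 1.0, "reject": False}
             for i, a in enumerate(names) for b in names[i + 1:]])
        return overall, pairs

    f_stat = (ss_between / df1) / (ss_within / df2) if ss_within > tol else float("inf")
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    overall = TestResult(float(f_stat), float(df1), p, effect, "one-way F")
    overall.effect["df_resid"] = df2

    tukey = pairwise_tukeyhsd(df[value_col].to_numpy(),
                              df[class_col].to_numpy(), alpha=0.05)
    rows = []
    for row in tukey.summary().data[1:]:
        g1, g2 = str(row[0]), str(row[1])
        rows.append({
            "group1": g1, "group2": g2,
            "meandiff": float(row[2]),
            "p_adj": float(row[3]),
            "p_raw": _pooled_t_p(groups[g1], groups[g2]),
            "reject": bool(row[-1]),
        })
    return overall, pd.DataFrame(rows)
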