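"""Group statistics with pinned small-sample behavior.

Thin wrappers around :mod:`scipy.stats` that fix tie/zero handling and the
exact-vs-approximate thresholds, so results are reproducible across
implementations.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatError

WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    df: tuple[int, ...] = ()
    alternative: str = "two-sided"
    group_labels: tuple[str, ...] = ()
    defined: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.defined and not (0.0 <= self.p_value <= 1.0):
            raise StatError(f"p-value out of [0,1]: {self.p_value}")


def wilcoxon_one_sample(values: Sequence[float], mu: float = 1.0) -> StatResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu``.

    Zeros (value == mu) are dropped per the signed-rank convention; the p
    value is exact for n <= 25 non-zero differences and normal-approximated
    above.  With fewer than 5 non-zero values the exact p cannot reach 0.05
    and a warning is emitted.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return StatResult("wilcoxon_one_sample", np.nan, np.nan, 0,
                          defined=False, note="all values equal mu")
    if n < 5:
        warnings.warn(
            f"n={n} non-zero differences: exact Wilcoxon p cannot fall below "
            f"{2 / 2**n:.4g}", stacklevel=2)
    method = "exact" if n <= WILCOXON_EXACT_MAX_N else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return StatResult("wilcoxon_one_sample", float(res.statistic),
                      float(res.pvalue), n)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) variant for two groups."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise StatError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if (a.size + b.size) <= 25 else "asymptotic")
    return StatResult("wilcoxon_rank_sum", float(res.statistic),
                      float(res.pvalue), a.size + b.size)


def kruskal_wallis(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H with tie correction, chi-squared reference, k-1 df."""
    if isinstance(groups, Mapping):
        labels = tuple(str(k) for k in groups)
        arrays = [np.asarray(v, float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, float) for v in groups]
        labels = tuple(f"group{i}" for i in range(len(arrays)))
    if len(arrays) < 2:
        raise StatError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise StatError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return StatResult("kruskal_wallis", 0.0, np.nan, n,
                          df=(len(arrays) - 1,), group_labels=labels,
                          defined=False, note="all observations identical")
    H, p = sps.kruskal(*arrays)
    return StatResult("kruskal_wallis", float(H), float(p), n,
                      df=(len(arrays) - 1,), group_labels=labels)


def linear_model_anova(response: Sequence[float], predictor: Sequence[float]) -> StatResult:
    """OLS of response on one predictor with the ANOVA F test of the slope.

    F = (SSR/1)/(SSE/(n-2)); a perfect fit (SSE = 0) is reported as an
    infinite-F flag with p = 0.
    """
    y = np.asarray(response, float)
    x = np.asarray(predictor, float)
    if y.size != x.size:
        raise StatError("response and predictor lengths differ")
    n = y.size
    if n < 3:
        raise StatError(f"need n >= 3, got {n}")
    if np.var(x) == 0:
        raise StatError("zero predictor variance")
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    yhat = ym + slope * (x - xm)
    sse = float(np.sum((y - yhat) ** 2))
    ssr = float(np.sum((yhat - ym) ** 2))
    if sse <= 0:
        return StatResult("linear_model_anova", float("inf"), 0.0, n,
                          df=(1, n - 2), note="perfect fit: SSE = 0")
    F = ssr / (sse / (n - 2))
    p = float(sps.f.sf(F, 1, n - 2))
    return StatResult("linear_model_anova", float(F), p, n, df=(1, n - 2))


def paired_t(values_a: Sequence[float], values_b: Sequence[float]) -> StatResult:
    """Paired t test on differences, df = n - 1."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size != b.size:
        raise StatError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise StatError(f"need n >= 2 pairs, got {n}")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return StatResult("paired_t", 0.0, 1.0, n, df=(n - 1,))
        return StatResult("paired_t", np.nan, np.nan, n, df=(n - 1,),
                          defined=False, note="zero-variance non-zero differences")
    res = sps.ttest_rel(a, b)
    return StatResult("paired_t", float(res.statistic), float(res.pvalue),
                      n, df=(n - 1,))


def firing_incidence(fired: pd.DataFrame) -> pd.Series:
    """Percentage of cells firing at least once per modality.

    ``fired`` is a boolean table, one row per cell and one column per
    modality.  Percentages are rounded to one decimal (3/60 -> 5.0,
    4/60 -> 6.7).
    """
    if fired.shape[0] == 0 or fired.shape[1] == 0:
        raise StatError("empty firing table")
    pct = 100.0 * fired.astype(bool).mean(axis=0)
    return pct.round(1)


def format_stat(r: StatResult) -> str:
    """Report-style rendering: statistics to 2 decimals, p to 4."""
    if not r.defined:
        return f"{r.test_name}: undefined ({r.note})"
    df = f"({', '.join(map(str, r.df))})" if r.df else ""
    return (f"{r.test_name}{df} = {r.statistic:.2f}, "
            f"p = {r.p_value:.4f}, n = {r.n}")
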