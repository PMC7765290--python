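"""Validation statistics: Pearson correlation, two-way ICCs, paired t-tests.

Pearson r carries a Fisher-z 95% CI and the usual t-based two-sided p;
correlation strength uses Cohen's strata on |r| (negligible < 0.1,
small < 0.3, medium < 0.5, large <= 1).  Inter-/intra-rater reliability
is the two-way mixed intraclass correlation in its consistency form,
computed from the targets x raters ANOVA decomposition: the
single-measure ICC(3,1) and average-measure ICC(3,k); the
absolute-agreement form is available behind a flag.  The two are linked
by the Spearman-Brown step-up relation aICC = k*sICC / (1 + (k-1)*sICC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "ICCResult",
    "PairedTestResult",
    "pearson",
    "icc_two_way",
    "paired_t",
    "classify_correlation",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci95: tuple[float, float]
    p: float
    strength: str


@dataclass(frozen=True)
class ICCResult:
    sicc: float
    aicc: float
    k_raters: int
    n_targets: int
    ms_rows: float
    ms_error: float
    form: str = "consistency"


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float


def classify_correlation(r: float) -> str:
    """Cohen's strength strata on |r|."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation coefficient {r} outside [-1, 1]")
    magnitude = abs(r)
    if magnitude >= 0.5:
        return "large"
    if magnitude >= 0.3:
        return "medium"
    if magnitude >= 0.1:
        return "small"
    return "negligible"


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with Fisher-z CI and t-based p.

    CI: tanh(atanh(r) +/- 1.96/sqrt(n-3)); p two-sided from
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(xa)
    if n < 3:
        raise ValueError(f"Pearson correlation needs n >= 3, got {n}")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values in correlation input")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in correlation input")

    r, p = stats.pearsonr(xa, ya)
    r = float(r)
    if abs(r) == 1.0:
        ci = (r, r)
    elif n > 3:
        z = math.atanh(r)
        half = 1.96 / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:  # n == 3: Fisher interval degenerate
        ci = (math.nan, math.nan)
    return CorrelationResult(r=r, n=n, ci95=ci, p=float(p),
                             strength=classify_correlation(r))


def icc_two_way(ratings, *, form: str = "consistency") -> ICCResult:
    """Two-way mixed ICC from a complete targets x raters grid.

    ``form='consistency'`` (default): sICC = ICC(3,1) and aICC =
    ICC(3,k) from the row and residual mean squares.
    ``form='agreement'``: the absolute-agreement variants, which also
    charge systematic rater offsets to disagreement.
    """
    grid = np.asarray(ratings, dtype=float)
    if grid.ndim != 2:
        raise ValueError("ratings must be a 2-D targets x raters grid")
    n, k = grid.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 targets and >= 2 raters, got {grid.shape}")
    if np.isnan(grid).any():
        raise ValueError("incomplete ratings grid (NaN present)")

    grand = grid.mean()
    row_means = grid.mean(axis=1)
    col_means = grid.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((grid - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if form == "consistency":
        denom_single = ms_rows + (k - 1) * ms_err
        sicc = (ms_rows - ms_err) / denom_single if denom_single != 0 else math.nan
        aicc = (ms_rows - ms_err) / ms_rows if ms_rows != 0 else math.nan
    elif form == "agreement":
        denom_single = ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
        sicc = (ms_rows - ms_err) / denom_single if denom_single != 0 else math.nan
        denom_avg = ms_rows + (ms_cols - ms_err) / n
        aicc = (ms_rows - ms_err) / denom_avg if denom_avg != 0 else math.nan
    else:
        raise ValueError("form must be 'consistency' or 'agreement'")

    return ICCResult(sicc=float(sicc), aicc=float(aicc), k_raters=k, n_targets=n,
                     ms_rows=float(ms_rows), ms_error=float(ms_err), form=form)


def paired_t(x_t0: Sequence[float], x_t1: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on complete cases; differences are t0 - t1.

    Identical samples (all differences zero) return t = 0, p = 1 as the
    continuous limit; a non-zero constant difference leaves p undefined
    and raises.
    """
    a = np.asarray(x_t0, dtype=float)
    b = np.asarray(x_t1, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equally long")
    n = len(a)
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2, got {n}")
    diff = a - b
    mean_diff = float(diff.mean())
    if np.std(diff, ddof=1) == 0:
        if mean_diff == 0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        raise ValueError("zero-variance non-zero differences: p undefined")
    res = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(res.statistic), df=n - 1,
                            p=float(res.pvalue), mean_diff=mean_diff)
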