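"""Cohort statistics: visit-pair changes, group summaries, pooled-t and
bootstrap confidence intervals, normality gating, and Fisher's exact test.

Inference is deliberately limited to 95% confidence intervals on the
between-group mean difference (no-exudation minus exudation), computed with
the equal-variance two-sample t interval, or — when Shapiro–Wilk rejects
normality in either group — with a seeded percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import DAYS_PER_MONTH

__all__ = [
    "GroupSummary",
    "CiResult",
    "visit_change",
    "summarize",
    "pooled_t_ci",
    "pooled_t_ci_from_samples",
    "bootstrap_ci",
    "normality_gate",
    "fisher_exact_2x2",
    "mann_whitney_p",
    "percent_smaller",
]


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    iqr: float


@dataclass
class CiResult:
    diff: float
    lo: float
    hi: float
    method: str  # pooled_t | bootstrap_percentile
    n1: int
    n2: int


def visit_change(v1: float, v2: float, days: float) -> tuple[float, float]:
    """Per-eye change between visits and the corresponding monthly rate.

    The rate uses a 30.44-day month (365.25 / 12).
    """
    if days <= 0:
        raise ValueError("days between visits must be positive")
    diff = v2 - v1
    return diff, diff / (days / DAYS_PER_MONTH)


def summarize(sample: Sequence[float]) -> GroupSummary:
    """Mean, SD (n−1), median, and IQR of one group's values."""
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 1:
        raise ValueError("empty sample")
    q75, q25 = np.percentile(x, [75, 25])
    return GroupSummary(
        n=len(x),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        median=float(np.median(x)),
        iqr=float(q75 - q25),
    )


def pooled_t_ci(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    level: float = 0.95,
) -> CiResult:
    """Equal-variance two-sample t confidence interval from summary statistics.

    ``diff = mean1 − mean2``; the pooled variance is
    ``sp² = ((n1−1)·sd1² + (n2−1)·sd2²) / (n1+n2−2)`` and the half-width is
    ``t_{1−α/2, n1+n2−2} · sp · sqrt(1/n1 + 1/n2)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    tcrit = sps.t.ppf(0.5 + level / 2.0, df)
    half = tcrit * sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    diff = mean1 - mean2
    return CiResult(diff=float(diff), lo=float(diff - half), hi=float(diff + half),
                    method="pooled_t", n1=n1, n2=n2)


def pooled_t_ci_from_samples(
    sample1: Sequence[float], sample2: Sequence[float], level: float = 0.95
) -> CiResult:
    x1, x2 = np.asarray(sample1, float), np.asarray(sample2, float)
    return pooled_t_ci(x1.mean(), x1.std(ddof=1), len(x1),
                       x2.mean(), x2.std(ddof=1), len(x2), level)


def bootstrap_ci(
    sample1: Sequence[float],
    sample2: Sequence[float],
    B: int = 2000,
    level: float = 0.95,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> CiResult:
    """Seeded percentile-bootstrap CI for the difference of group means.

    Both groups are resampled with replacement ``B`` times; the interval is
    the (α/2, 1−α/2) percentile range of the resampled mean differences.
    """
    x1, x2 = np.asarray(sample1, float), np.asarray(sample2, float)
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("samples must be non-empty")
    if B < 100:
        import warnings

        warnings.warn(f"B={B} bootstrap resamples is very low", stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng(seed)
    m1 = rng.choice(x1, size=(B, len(x1)), replace=True).mean(axis=1)
    m2 = rng.choice(x2, size=(B, len(x2)), replace=True).mean(axis=1)
    diffs = m1 - m2
    alpha = 1.0 - level
    lo, hi = np.percentile(diffs, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    return CiResult(diff=float(x1.mean() - x2.mean()), lo=float(lo), hi=float(hi),
                    method="bootstrap_percentile", n1=len(x1), n2=len(x2))


def normality_gate(
    sample1: Sequence[float],
    sample2: Sequence[float],
    alpha: float = 0.05,
    mode: str = "per_group",
) -> dict:
    """Choose the CI method by Shapiro–Wilk.

    ``per_group`` (default) tests each group; ``pooled_residuals`` tests the
    mean-centered pooled residuals.  If any test rejects at ``alpha``, the
    percentile bootstrap is selected, otherwise the pooled-t interval.
    """
    x1, x2 = np.asarray(sample1, float), np.asarray(sample2, float)
    if len(x1) < 3 or len(x2) < 3:
        raise ValueError("Shapiro–Wilk needs n >= 3 per sample")
    if mode == "per_group":
        pvals = [sps.shapiro(x1).pvalue, sps.shapiro(x2).pvalue]
    elif mode == "pooled_residuals":
        resid = np.concatenate([x1 - x1.mean(), x2 - x2.mean()])
        pvals = [sps.shapiro(resid).pvalue]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    reject = any(p < alpha for p in pvals)
    return {
        "method": "bootstrap_percentile" if reject else "pooled_t",
        "shapiro_pvalues": pvals,
        "alpha": alpha,
    }


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2×2 table [[a, b], [c, d]].

    Enumerates all tables with the observed margins; the p-value is the sum
    of hypergeometric probabilities of tables no more probable than the
    observed one.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("cell counts must be non-negative integers")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero table")
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    # hypergeometric log-pmf over the support (margins fixed, k = cell a)
    from scipy.special import gammaln

    def logc(m, k):
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    logpmf = logc(r1, support) + logc(r2, c1 - support) - logc(n, c1)
    pmf = np.exp(logpmf)
    p_obs = pmf[a - kmin]
    # tolerance guards against ties broken by floating-point rounding
    total = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
    return float(min(1.0, total))


def mann_whitney_p(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    """Two-sided Mann–Whitney U p-value (utility for visit-interval checks)."""
    return float(sps.mannwhitneyu(sample1, sample2, alternative="two-sided").pvalue)


def percent_smaller(mean_ref: float, mean_other: float) -> int:
    """How much smaller ``mean_other`` is than ``mean_ref``, as a rounded
    percentage of the reference mean."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return int(round(100.0 * (mean_ref - mean_other) / mean_ref))
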