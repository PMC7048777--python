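"""Inference from published summary statistics (mean, SEM, n).

Group comparisons reported only as ``mean ± SEM (n)`` can be re-analysed
without the raw data: a one-way ANOVA needs nothing beyond the per-group
means, SDs (= SEM * sqrt(n)) and sizes, and the two-sample t-test likewise.
This module reconstructs those tests exactly, plus the p-value adjustments
used downstream by the qPCR comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "anova_from_summary",
    "ttest_from_summary",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class GroupSummary:
    """One group's published summary: mean, SEM and size."""

    mean: float
    sem: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_sd(cls, mean: float, sd: float, n: int, label: str = "") -> "GroupSummary":
        """Build from a mean ± SD report (converts SD to SEM)."""
        return cls(mean=mean, sem=sd / np.sqrt(n), n=n, label=label)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    ss_between: float
    ss_within: float

    @property
    def eta_squared(self) -> float:
        return self.ss_between / (self.ss_between + self.ss_within)


def anova_from_summary(groups: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA computed from (mean, SEM, n) triples.

    SS_between = sum n_i (m_i - m̄)^2 about the size-weighted grand mean;
    SS_within = sum (n_i - 1) * sd_i^2; F = MS_between / MS_within with
    df = (k-1, N-k).  Identical to a standard one-way ANOVA on any raw data
    realising exactly these summaries.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    means = np.array([g.mean for g in groups])
    ns = np.array([g.n for g in groups])
    sds = np.array([g.sd for g in groups])
    N, k = int(ns.sum()), len(groups)
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw == 0 and ssb == 0:
        raise ValueError("F undefined: no between- or within-group variance")
    if ssw == 0:
        raise ValueError("F undefined: zero within-group variance")
    F = (ssb / (k - 1)) / (ssw / (N - k))
    p = float(stats.f.sf(F, k - 1, N - k))
    return AnovaResult(F=float(F), df1=k - 1, df2=N - k, p=p,
                       ss_between=ssb, ss_within=ssw)


def ttest_from_summary(
    a: GroupSummary,
    b: GroupSummary,
    variant: str = "pooled",
    tails: int = 2,
) -> tuple[float, float, float]:
    """Two-sample t-test from summaries; returns (t, df, p).

    ``variant='pooled'`` uses the pooled-variance statistic with
    df = n_a + n_b - 2; ``'welch'`` uses the Welch statistic with
    Satterthwaite df.  ``tails`` is 2 (default) or 1.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    va, vb = a.sd**2, b.sd**2
    if va == 0 and vb == 0 and a.mean == b.mean:
        raise ValueError("t undefined: zero variance in both groups, equal means")
    t_stat, _ = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = a.n + b.n - 2.0
    else:
        u, w = va / a.n, vb / b.n
        df = (u + w) ** 2 / (u**2 / (a.n - 1) + w**2 / (b.n - 1))
    p = min(1.0, tails * float(stats.t.sf(abs(t_stat), df)))
    return float(t_stat), float(df), p


_METHOD_MAP = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "bh": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "benjamini-hochberg": "fdr_bh",
}


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment (Bonferroni, Holm, Benjamini–Hochberg).

    Input order is preserved; adjusted values are capped at 1 and are never
    below the raw p-values for these methods.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = method.lower()
    if key not in _METHOD_MAP:
        raise ValueError(f"unsupported method {method!r}")
    _, adj, _, _ = multipletests(p, method=_METHOD_MAP[key])
    return adj
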