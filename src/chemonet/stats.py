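"""Shared statistical primitives: paired/Welch contrasts, Spearman, BH-FDR,
Mann-Whitney and chi-square tests.

Thin, validated wrappers over scipy/statsmodels with the result fields the
pipeline's tables carry (estimate, SE, t, p, FDR, effect size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneContrast",
    "CorrelationResult",
    "paired_t_test",
    "welch_t_test",
    "spearman",
    "bh_fdr",
    "mann_whitney",
    "chisq_contingency",
]


@dataclass
class GeneContrast:
    """Differential statistics for one gene between two groups (log2 units)."""

    gene: str
    mean_diff: float
    se: float
    t_stat: float
    p: float
    cohens_d: float
    n: int
    fdr: float = np.nan


@dataclass
class CorrelationResult:
    gene: str
    variable: str
    rho: float
    p: float
    n: int
    fdr: float = np.nan


def paired_t_test(x, y, gene: str = "") -> GeneContrast:
    """Two-tailed paired t-test with Cohen's d on the differences.

    t = mean(d) / (sd(d)/sqrt(n)) on d = x - y (sample SD, n-1 df);
    cohens_d = mean(d)/sd(d).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError(f"degenerate differences (zero variance){' for ' + gene if gene else ''}")
    se = sd / np.sqrt(n)
    t = d.mean() / se
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return GeneContrast(
        gene=gene, mean_diff=float(d.mean()), se=float(se), t_stat=float(t), p=float(p),
        cohens_d=float(d.mean() / sd), n=n,
    )


def welch_t_test(a, b, gene: str = "") -> GeneContrast:
    """Welch two-sample t-test, a vs b; mean_diff = mean(a) - mean(b).

    Cohen's d uses the pooled SD; the (mean_diff, se) pair is the input
    expected by the Monte-Carlo reaction-regulation step.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 samples")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = float(np.sqrt(va / a.size + vb / b.size))
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
    return GeneContrast(
        gene=gene, mean_diff=float(a.mean() - b.mean()), se=se, t_stat=float(t), p=float(p),
        cohens_d=d, n=a.size + b.size,
    )


def spearman(x, y, gene: str = "", variable: str = "") -> CorrelationResult:
    """Spearman rank correlation (midranks for ties, p by t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(gene=gene, variable=variable, rho=float(rho), p=float(p), n=x.size)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact null for small tie-free samples.

    Returns (U of the first group, p).  Exact enumeration is used when
    min(n1, n2) <= 8 and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chisq_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns (chi2, df, p); zero marginal rows/columns are rejected.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
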