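"""Cluster profiling: differential expression, ssGSEA scoring and contrasts.

The chemokine-high vs chemokine-low clusters are characterised by
genome-wide Welch t-tests with a fold filter (FDR < 0.05 and linear fold
> 1.25 in either direction), single-sample gene-set enrichment (ssGSEA)
score contrasts, infiltration contrasts (Mann-Whitney) and categorical
contrasts (chi-square).

The ssGSEA score of a set S in one sample follows the weighted
Kolmogorov-Smirnov running sum: genes are ranked by decreasing
expression, in-set steps are weighted by rank^alpha (alpha = 0.25 by
default) and the enrichment score is the sum of the running difference
between the in-set and out-of-set cumulative distributions.  Scores are
rank-based, hence invariant to monotone transforms of each sample's
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import ExpressionCohort, GeneSetCollection
from .stats import bh_fdr, chisq_contingency, mann_whitney, welch_t_test

__all__ = [
    "differential_expression",
    "ssgsea",
    "SsgseaScores",
    "compare_scores",
    "compare_infiltration",
    "mann_whitney",
    "chisq_contingency",
]

FOLD_FILTER = 1.25


def differential_expression(
    cohort: ExpressionCohort,
    assignments: pd.Series,
    high: str = "high",
    low: str = "low",
    fold_filter: float = FOLD_FILTER,
) -> pd.DataFrame:
    """Genome-wide Welch t-test, high vs low cluster.

    Returns a frame indexed by gene with ``mean_diff`` (log2 units) and
    ``se`` — the pair consumed unchanged by the metabolic-regulation
    step — plus t, p, FDR, Cohen's d and a ``regulated`` flag
    (FDR < 0.05 and linear fold > ``fold_filter`` or < 1/``fold_filter``).
    """
    ids_high = [s for s in assignments.index[assignments == high] if s in cohort.values.columns]
    ids_low = [s for s in assignments.index[assignments == low] if s in cohort.values.columns]
    if len(ids_high) < 3 or len(ids_low) < 3:
        raise ValueError("each cluster needs >= 3 samples")
    a = cohort.values[ids_high].to_numpy(float)
    b = cohort.values[ids_low].to_numpy(float)
    n1, n2 = a.shape[1], b.shape[1]
    t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se = np.sqrt(va / n1 + vb / n2)
    pooled = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cohens_d = np.where(pooled > 0, mean_diff / pooled, 0.0)
    table = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "se": se,
            "t_stat": t,
            "p": p,
            "cohens_d": cohens_d,
            "n": n1 + n2,
        },
        index=cohort.values.index,
    )
    table["fdr"] = bh_fdr(np.nan_to_num(table["p"].to_numpy(), nan=1.0))
    log2_cut = np.log2(fold_filter)
    table["regulated"] = (table["fdr"] < 0.05) & (table["mean_diff"].abs() > log2_cut)
    table["direction"] = np.where(table["mean_diff"] > 0, "up", "down")
    return table


@dataclass
class SsgseaScores:
    """Signatures × samples enrichment-score matrix with scoring metadata."""

    scores: pd.DataFrame
    alpha: float = 0.25
    normalized: bool = True


def _ssgsea_sample(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment score for one sample (genes in fixed order)."""
    G = expr.size
    order = np.argsort(-expr, kind="stable")  # decreasing expression; stable tie-break
    ranks = np.empty(G)
    ranks[order] = np.arange(G, 0, -1)  # top-expressed gene has rank G
    mask = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w[~mask] = 0.0
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~mask) / (G - mask.sum())
    return float(np.sum(p_in - p_out))


def ssgsea(
    cohort: ExpressionCohort,
    gene_sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> SsgseaScores:
    """Single-sample gene-set enrichment scores for every set and sample.

    Each set must share at least one but not all genes with the cohort
    (the out-of-set distribution is undefined otherwise).  With
    ``normalize`` the whole score matrix is divided by its range
    (max - min), the usual cross-sample normalisation.
    """
    genes = list(cohort.values.index)
    lookup = {g.strip().casefold(): i for i, g in enumerate(genes)}
    masks = {}
    for name, members in gene_sets.sets.items():
        idx = sorted({lookup[m.strip().casefold()] for m in members if m.strip().casefold() in lookup})
        if not idx:
            raise ValueError(f"gene set {name!r} shares no genes with the cohort")
        if len(idx) == len(genes):
            raise ValueError(f"gene set {name!r} covers every cohort gene")
        mask = np.zeros(len(genes), dtype=bool)
        mask[idx] = True
        masks[name] = mask
    X = cohort.values.to_numpy(float)
    out = np.empty((len(masks), X.shape[1]))
    for j in range(X.shape[1]):
        col = X[:, j]
        for i, mask in enumerate(masks.values()):
            out[i, j] = _ssgsea_sample(col, mask, alpha)
    scores = pd.DataFrame(out, index=list(masks), columns=cohort.values.columns)
    if normalize:
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    return SsgseaScores(scores=scores, alpha=alpha, normalized=normalize)


def compare_scores(
    scores: SsgseaScores, assignments: pd.Series, high: str = "high", low: str = "low"
) -> pd.DataFrame:
    """Welch t contrast of ssGSEA scores per signature, FDR across signatures."""
    ids_high = [s for s in assignments.index[assignments == high] if s in scores.scores.columns]
    ids_low = [s for s in assignments.index[assignments == low] if s in scores.scores.columns]
    if len(ids_high) < 3 or len(ids_low) < 3:
        raise ValueError("each cluster needs >= 3 samples")
    rows = []
    for name in scores.scores.index:
        c = welch_t_test(
            scores.scores.loc[name, ids_high].to_numpy(float),
            scores.scores.loc[name, ids_low].to_numpy(float),
            gene=name,
        )
        rows.append({"signature": name, "mean_diff": c.mean_diff, "se": c.se,
                     "t_stat": c.t_stat, "p": c.p, "cohens_d": c.cohens_d, "n": c.n})
    table = pd.DataFrame(rows).set_index("signature")
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table["direction"] = np.where(table["mean_diff"] > 0, "up", "down")
    return table


def compare_infiltration(
    infiltration_scores: pd.DataFrame, assignments: pd.Series, high: str = "high", low: str = "low"
) -> pd.DataFrame:
    """Mann-Whitney contrast of infiltration estimates per cell type."""
    ids_high = [s for s in assignments.index[assignments == high] if s in infiltration_scores.columns]
    ids_low = [s for s in assignments.index[assignments == low] if s in infiltration_scores.columns]
    if not ids_high or not ids_low:
        raise ValueError("empty cluster")
    rows = []
    for ct in infiltration_scores.index:
        u, p = mann_whitney(
            infiltration_scores.loc[ct, ids_high].to_numpy(float),
            infiltration_scores.loc[ct, ids_low].to_numpy(float),
        )
        med_diff = float(
            np.median(infiltration_scores.loc[ct, ids_high]) - np.median(infiltration_scores.loc[ct, ids_low])
        )
        rows.append({"cell_type": ct, "u_stat": u, "p": p, "median_diff": med_diff})
    table = pd.DataFrame(rows).set_index("cell_type")
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return table
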