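"""Chemokine screening: tumor enrichment plus infiltration correlation.

Candidate chemokine genes are screened with two gates, mirroring how
tumor-relevant chemokines are usually shortlisted: (a) enrichment in
tumor versus donor-matched normal tissue (paired t-test, FDR < 0.05, and
at least four-fold, i.e. mean log2 difference >= 2) and (b) strong
monotone association with CD8 T-cell infiltration (Spearman rho > 0.6 at
FDR < 0.05).  Both statistics are always reported for every candidate so
the gate is transparent.  FDR correction is applied per question (all
candidates at once) within the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import ExpressionCohort, InfiltrationTable
from .stats import CorrelationResult, GeneContrast, bh_fdr, paired_t_test, spearman

__all__ = ["ScreenResult", "screen_chemokines", "correlation_network",
           "paired_t_test", "spearman", "bh_fdr"]

FOLD_THRESHOLD_LOG2 = 2.0  # four-fold on the linear scale
RHO_THRESHOLD = 0.6
FDR_THRESHOLD = 0.05


@dataclass
class ScreenResult:
    selected: list[str]
    stats: pd.DataFrame  # per-gene enrichment + correlation statistics
    not_evaluated: list[str] = field(default_factory=list)


def _paired_arrays(cohort: ExpressionCohort, gene_row: str) -> tuple[np.ndarray, np.ndarray]:
    meta = cohort.sample_meta
    tumor = meta[meta["tissue"] == "tumor"]
    normal = meta[meta["tissue"] == "normal"]
    donors = sorted(set(tumor["donor_id"].dropna()) & set(normal["donor_id"].dropna()))
    t_ids = [tumor.index[tumor["donor_id"] == d][0] for d in donors]
    n_ids = [normal.index[normal["donor_id"] == d][0] for d in donors]
    row = cohort.values.loc[gene_row]
    return row[t_ids].to_numpy(float), row[n_ids].to_numpy(float)


def screen_chemokines(
    cohort: ExpressionCohort,
    infiltration: InfiltrationTable,
    candidates: Sequence[str],
    cd8_label: str = "CD8 T cell",
    fold_log2: float = FOLD_THRESHOLD_LOG2,
    rho_min: float = RHO_THRESHOLD,
    fdr_max: float = FDR_THRESHOLD,
) -> ScreenResult:
    """Apply the two-gate chemokine screen to ``candidates``.

    ``cohort`` must contain donor-paired tumor/normal samples;
    ``infiltration`` must carry a ``cd8_label`` row covering the tumor
    samples.  Candidates absent from the cohort are listed under
    ``not_evaluated`` rather than silently dropped.
    """
    found, missing = cohort.find_genes(candidates)
    if not cohort.normal_samples():
        raise ValueError("screen requires donor-paired normal samples")
    if cd8_label not in infiltration.scores.index:
        raise ValueError(f"infiltration table lacks {cd8_label!r}")
    tumor_ids = [s for s in cohort.tumor_samples() if s in infiltration.scores.columns]
    cd8 = infiltration.scores.loc[cd8_label, tumor_ids].to_numpy(float)

    contrasts: list[GeneContrast] = []
    correlations: list[CorrelationResult] = []
    for cand in candidates:
        if cand in missing:
            continue
        row = found[cand]
        x, y = _paired_arrays(cohort, row)
        if x.size == 0:
            raise ValueError("no complete tumor/normal pairs")
        contrasts.append(paired_t_test(x, y, gene=cand))
        expr = cohort.values.loc[row, tumor_ids].to_numpy(float)
        correlations.append(spearman(expr, cd8, gene=cand, variable=cd8_label))

    stats = pd.DataFrame(
        {
            "gene": [c.gene for c in contrasts],
            "mean_diff": [c.mean_diff for c in contrasts],
            "se": [c.se for c in contrasts],
            "t_stat": [c.t_stat for c in contrasts],
            "p_paired": [c.p for c in contrasts],
            "cohens_d": [c.cohens_d for c in contrasts],
            "n_pairs": [c.n for c in contrasts],
            "rho_cd8": [r.rho for r in correlations],
            "p_rho": [r.p for r in correlations],
        }
    ).set_index("gene")
    if len(stats):
        stats["fdr_paired"] = bh_fdr(stats["p_paired"].to_numpy())
        stats["fdr_rho"] = bh_fdr(stats["p_rho"].to_numpy())
        stats["selected"] = (
            (stats["fdr_paired"] < fdr_max)
            & (stats["mean_diff"] >= fold_log2)
            & (stats["rho_cd8"] > rho_min)
            & (stats["fdr_rho"] < fdr_max)
        )
    else:
        stats["fdr_paired"] = stats["fdr_rho"] = []
        stats["selected"] = []
    return ScreenResult(
        selected=list(stats.index[stats["selected"]]),
        stats=stats,
        not_evaluated=missing,
    )


def correlation_network(
    cohort: ExpressionCohort,
    genes: Sequence[str],
    infiltration: InfiltrationTable,
    rho_star: float = 0.4,
) -> pd.DataFrame:
    """Spearman co-expression / infiltration network edge list.

    Edges join gene-gene and gene-cell-type pairs whose absolute Spearman
    rho exceeds ``rho_star`` (default 0.4, moderate-to-large strength);
    the signed rho is reported.  Returned as a tidy frame
    (node_a, node_b, rho) usable directly with
    ``networkx.from_pandas_edgelist``.
    """
    if not 0 <= rho_star <= 1:
        raise ValueError("rho_star must lie in [0, 1]")
    found, missing = cohort.find_genes(genes)
    if missing:
        raise ValueError(f"genes absent from cohort: {missing}")
    tumor_ids = [s for s in cohort.tumor_samples() if s in infiltration.scores.columns]
    frames = {g: cohort.values.loc[found[g], tumor_ids].to_numpy(float) for g in genes}
    for ct in infiltration.cell_types:
        frames[ct] = infiltration.scores.loc[ct, tumor_ids].to_numpy(float)
    names = list(frames)
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if a in infiltration.cell_types and b in infiltration.cell_types:
                continue  # network joins genes with genes/cell types only
            res = spearman(frames[a], frames[b], gene=a, variable=b)
            if abs(res.rho) > rho_star:
                edges.append({"node_a": a, "node_b": b, "rho": res.rho, "p": res.p})
    return pd.DataFrame(edges, columns=["node_a", "node_b", "rho", "p"])
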