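"""Reaction-level metabolic regulation from gene-level differential expression.

Given per-gene log2 fold changes and their standard errors (the output of
the cluster differential-expression step), each reaction's regulation is
inferred by evaluating its GPR rule on fold-change activities: in each
Monte-Carlo draw the gene log2 fold changes are perturbed with their
standard errors, exponentiated to linear fold activities (2^δ), and the
GPR algebra (AND = min, OR = sum) yields the reaction's activity in the
"high" condition; the "low" condition evaluates every gene at activity 1,
so a reaction with no expression change has regulation exactly 0.  The
draw distribution supplies the SD, percentile 95% CI and a two-sided
empirical sign p-value; reactions are then FDR-corrected and called
activated / inhibited / unchanged.

One shared draw matrix is used for all reactions, so reactions sharing
genes co-vary across draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import MetabolicModelSpec
from .gpr import parse_gpr
from .stats import bh_fdr

__all__ = ["estimate_reaction_regulation", "summarize_subsystems", "RegulationResult"]

logger = logging.getLogger(__name__)


@dataclass
class RegulationResult:
    """Reaction-level regulation table plus bookkeeping of skipped reactions."""

    table: pd.DataFrame  # one row per reaction with a GPR rule
    skipped: list[str]  # reactions without a GPR rule
    neutral_genes: list[str]  # genes defaulted to (0, 0) for lack of a DE estimate


def estimate_reaction_regulation(
    model: MetabolicModelSpec,
    contrasts: pd.DataFrame,
    n_draws: int = 1000,
    seed: int | None = 0,
    missing_policy: str = "neutral",
) -> RegulationResult:
    """Monte-Carlo GPR regulation estimates for every reaction of ``model``.

    Parameters
    ----------
    contrasts
        DataFrame indexed by gene id with columns ``mean_diff`` (log2 fold
        change, high vs low) and ``se`` (its standard error).
    n_draws
        Monte-Carlo draws (>= 100).
    missing_policy
        ``"neutral"``: genes absent from ``contrasts`` get (0, 0) with a
        warning; ``"strict"``: raise instead.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if missing_policy not in ("neutral", "strict"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    model_genes = list(model.genes)
    present = [g for g in model_genes if g in contrasts.index]
    absent = [g for g in model_genes if g not in contrasts.index]
    if absent:
        if missing_policy == "strict":
            raise KeyError(f"genes without DE estimates: {absent[:10]}")
        logger.warning("%d model genes lack DE estimates; treated as neutral (0, 0)", len(absent))

    mu = pd.Series(0.0, index=model_genes)
    se = pd.Series(0.0, index=model_genes)
    mu.loc[present] = contrasts.loc[present, "mean_diff"].astype(float)
    se.loc[present] = contrasts.loc[present, "se"].astype(float)

    rng = np.random.default_rng(seed)
    # one δ matrix per run: genes sharing reactions stay correlated across draws
    delta = mu.to_numpy()[:, None] + se.to_numpy()[:, None] * rng.standard_normal(
        (len(model_genes), n_draws)
    )
    activity = {g: np.exp2(delta[i]) for i, g in enumerate(model_genes)}
    baseline = {g: 1.0 for g in model_genes}

    rows = []
    skipped = []
    for rxn in model.reactions:
        if not rxn.has_gpr:
            skipped.append(rxn.reaction_id)
            continue
        tree = parse_gpr(rxn.gpr)
        high = np.asarray(tree.evaluate(activity), dtype=float)
        low = float(tree.evaluate(baseline))
        reg = np.log2(high / low)
        point = float(reg.mean())
        sd = float(reg.std(ddof=1))
        ci_low, ci_high = np.percentile(reg, [2.5, 97.5])
        n_le = int((reg <= 0).sum())
        n_ge = int((reg >= 0).sum())
        p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_draws + 1))
        rows.append(
            {
                "reaction_id": rxn.reaction_id,
                "subsystem": rxn.subsystem or "unassigned",
                "log2_reg": point,
                "sd": sd,
                "ci_low": float(ci_low),
                "ci_high": float(ci_high),
                "p": p,
                "n_draws": n_draws,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        table["status"] = "unchanged"
        table.loc[(table["fdr"] < 0.05) & (table["log2_reg"] > 0), "status"] = "activated"
        table.loc[(table["fdr"] < 0.05) & (table["log2_reg"] < 0), "status"] = "inhibited"
        table = table.set_index("reaction_id")
    return RegulationResult(table=table, skipped=skipped, neutral_genes=absent)


def summarize_subsystems(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subsystem fractions of significantly activated / inhibited reactions."""
    rows = []
    for subsystem, grp in table.groupby("subsystem"):
        n = len(grp)
        rows.append(
            {
                "subsystem": subsystem,
                "n_reactions": n,
                "frac_activated": float((grp["status"] == "activated").sum()) / n,
                "frac_inhibited": float((grp["status"] == "inhibited").sum()) / n,
            }
        )
    return pd.DataFrame(rows).set_index("subsystem").sort_index()
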