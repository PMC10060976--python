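"""Synthetic multi-cohort transcriptome generator with full ground truth.

Emulates the statistical structure the chemokine analysis assumes: two
latent tumor clusters ("high"/"low") separated on an 8-gene chemokine
panel, donor-paired tumor/normal samples with planted tumor enrichment of
the panel, CD8 T-cell infiltration scores tied to mean panel expression
through a logistic link, co-regulated IFN/exhaustion, OXPHOS/TCA/FAO and
tryptophan gene modules, survival times with a configurable (default
null) cluster effect, and a toy metabolic model whose true reaction
regulation follows analytically from the planted gene effects.

Expression model, per gene g and tumor sample i::

    x_gi = mu_g + cohort_shift_g + enrich_g + z_i * effect_g + eps,   eps ~ N(0, sigma)

with z_i ~ Bernoulli(pi) the latent cluster, effect_g the planted
high-vs-low log2 shift and enrich_g the tumor-vs-normal log2 enrichment
(chemokine panel only; enrichment attributable to the tumor per se,
beyond the cluster effect).  Matched normals share the donor's baseline
but carry neither term, so the population tumor-vs-normal contrast of a
panel gene is enrich_g + pi * effect_g and the cluster contrast is
effect_g.

All cohorts of one design share gene baselines and effects and differ by
a per-cohort baseline offset, so cross-cohort model projection is a
meaningful test.  Identical design + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .core_data import (
    ExpressionCohort,
    InfiltrationTable,
    MetabolicModelSpec,
    ReactionSpec,
)
from .gpr import parse_gpr

__all__ = ["SimulationDesign", "GroundTruth", "CohortBundle", "simulate_cohort",
           "simulate_paired_normals", "simulate_survival", "emit_toy_metabolic_model",
           "simulate_study"]

DEFAULT_PANEL = ("CXCL9", "CXCL10", "CXCL11", "CXCR3", "CXCL13", "CXCR5", "XCL1", "XCR1")

#: gene-module sizes: large enough for stable ssGSEA scores, small enough for desk scale
DEFAULT_MODULE_SIZES = {"ifn_exhaustion": 40, "oxphos_tca_fao": 40, "trp": 10}
DEFAULT_MODULE_SHIFTS = {"ifn_exhaustion": 1.0, "oxphos_tca_fao": -1.0, "trp": 1.0}


@dataclass
class SimulationDesign:
    """Planted parameters of the synthetic study (log2 units throughout)."""

    n_samples: int = 200
    n_cohorts: int = 2
    n_genes: int = 300
    chemokine_panel: tuple[str, ...] = DEFAULT_PANEL
    cluster_prevalence: float = 0.5
    panel_shift: float = 2.0  # high-vs-low log2 shift of panel genes
    module_shifts: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MODULE_SHIFTS))
    module_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_MODULE_SIZES))
    tumor_enrichment: float = 2.0  # panel log2 shift tumor vs paired normal (four-fold)
    paired_fraction: float = 0.5
    infiltration_link: float = 1.0  # logistic slope of CD8 score on mean panel expression
    infiltration_noise: float = 0.1
    noise_sd: float = 1.0
    baseline_hazard: float = np.log(2) / 1825.0  # per day; ~5-year median OS
    cluster_log_hr: float = 0.0  # default: null survival effect
    censoring_rate: float = 0.4
    cohort_shift_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cluster_prevalence < 1:
            raise ValueError("cluster_prevalence must lie in (0, 1)")
        if self.panel_shift < 0:
            raise ValueError("panel_shift must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.paired_fraction <= 1:
            raise ValueError("paired_fraction must lie in [0, 1]")
        if self.n_samples < 10:
            raise ValueError("n_samples < 10: too small for downstream analyses")

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=seed)

    # -- deterministic gene layout (independent of RNG) --
    def gene_names(self) -> list[str]:
        names = list(self.chemokine_panel)
        for module, size in self.module_sizes.items():
            prefix = {"ifn_exhaustion": "IFNEXH", "oxphos_tca_fao": "METAB", "trp": "TRP"}.get(
                module, module.upper()
            )
            names += [f"{prefix}{i:03d}" for i in range(1, size + 1)]
        n_fill = self.n_genes - len(names)
        if n_fill < 0:
            raise ValueError("n_genes smaller than panel + modules")
        names += [f"NULL{i:04d}" for i in range(1, n_fill + 1)]
        return names

    def module_genes(self, module: str) -> list[str]:
        prefix = {"ifn_exhaustion": "IFNEXH", "oxphos_tca_fao": "METAB", "trp": "TRP"}[module]
        return [g for g in self.gene_names() if g.startswith(prefix)]

    def gene_effects(self) -> pd.Series:
        """True high-vs-low log2 effect per gene."""
        eff = pd.Series(0.0, index=self.gene_names())
        eff[list(self.chemokine_panel)] = self.panel_shift
        for module, shift in self.module_shifts.items():
            eff[self.module_genes(module)] = shift
        return eff


@dataclass
class GroundTruth:
    """Planted parameters behind one simulated cohort."""

    cluster_labels: pd.Series  # tumor sample -> 'high' / 'low'
    gene_effects: pd.Series  # true high-vs-low log2 shift per gene
    tumor_enrichment: pd.Series  # true tumor-vs-normal log2 shift per gene
    reaction_regulation: pd.Series  # true log2 regulation per toy-model reaction
    cluster_log_hr: float


@dataclass
class CohortBundle:
    cohort: ExpressionCohort
    infiltration: InfiltrationTable
    truth: GroundTruth


_STREAMS = {"expression": 1, "survival": 2, "stage": 3, "infiltration": 4, "normals": 5}


def _rng_for(design: SimulationDesign, cohort_index: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence([design.seed, cohort_index, _STREAMS[stream]])
    return np.random.default_rng(ss)


def _baselines(design: SimulationDesign) -> pd.Series:
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2**20]))
    genes = design.gene_names()
    return pd.Series(rng.normal(6.0, 1.0, size=len(genes)), index=genes)


def simulate_cohort(design: SimulationDesign, cohort_index: int = 0) -> CohortBundle:
    """Simulate one cohort's tumor samples with infiltration and ground truth."""
    genes = design.gene_names()
    mu = _baselines(design)
    cohort_id = f"SYN{cohort_index:02d}"
    rng = _rng_for(design, cohort_index, "expression")
    shift = pd.Series(
        rng.normal(0.0, design.cohort_shift_sd, size=len(genes)) if cohort_index > 0 else 0.0,
        index=genes,
    )
    n = design.n_samples
    z = (rng.random(n) < design.cluster_prevalence).astype(int)
    effects = design.gene_effects()
    enrich = pd.Series(0.0, index=genes)
    enrich[list(design.chemokine_panel)] = design.tumor_enrichment

    mean = (
        mu.to_numpy()[:, None]
        + shift.to_numpy()[:, None]
        + enrich.to_numpy()[:, None]
        + np.outer(effects.to_numpy(), z)
    )
    values = mean + rng.normal(0.0, design.noise_sd, size=mean.shape)
    samples = [f"{cohort_id}_T{i + 1:03d}" for i in range(n)]
    labels = pd.Series(np.where(z == 1, "high", "low"), index=samples, name="true_cluster")

    os_time, os_event = simulate_survival(design, labels, rng=_rng_for(design, cohort_index, "survival"))
    meta = pd.DataFrame(
        {
            "tissue": "tumor",
            "donor_id": [f"{cohort_id}_D{i + 1:03d}" for i in range(n)],
            "os_time": os_time.to_numpy(),
            "os_event": os_event.to_numpy(),
            "stage": _rng_for(design, cohort_index, "stage").choice(
                ["T1", "T2", "T3", "T4"], size=n, p=[0.5, 0.15, 0.25, 0.1]
            ),
        },
        index=samples,
    )
    cohort = ExpressionCohort(
        cohort_id=cohort_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_meta=meta,
    )
    infiltration = _simulate_infiltration(design, cohort_index, cohort)
    model, true_reg = emit_toy_metabolic_model(design)
    truth = GroundTruth(
        cluster_labels=labels,
        gene_effects=effects,
        tumor_enrichment=enrich,
        reaction_regulation=true_reg,
        cluster_log_hr=design.cluster_log_hr,
    )
    return CohortBundle(cohort=cohort, infiltration=infiltration, truth=truth)


def _simulate_infiltration(
    design: SimulationDesign, cohort_index: int, cohort: ExpressionCohort
) -> InfiltrationTable:
    """CD8 score = logistic(slope * centered mean panel expression) + noise.

    Decoy cell types carry independent noise so screening has true
    negatives at the cell-type level too.
    """
    rng = _rng_for(design, cohort_index, "infiltration")
    panel = cohort.values.loc[list(design.chemokine_panel)]
    mean_panel = panel.mean(axis=0)
    centered = mean_panel - mean_panel.mean()
    cd8 = expit(design.infiltration_link * centered) + rng.normal(
        0.0, design.infiltration_noise, size=cohort.n_samples
    )
    scores = pd.DataFrame(
        {
            "CD8 T cell": np.maximum(cd8, 0.0),
            "Treg": np.maximum(rng.normal(0.3, 0.1, cohort.n_samples), 0.0),
            "Macrophage": np.maximum(rng.normal(0.5, 0.15, cohort.n_samples), 0.0),
            "B cell": np.maximum(rng.normal(0.2, 0.08, cohort.n_samples), 0.0),
        },
        index=cohort.samples,
    ).T
    return InfiltrationTable(scores=scores)


def simulate_paired_normals(design: SimulationDesign, cohort_index: int = 0) -> ExpressionCohort:
    """Donor-matched normal samples for ``paired_fraction`` of tumor donors.

    Normals share the cohort baselines but carry neither the tumor
    enrichment nor the cluster effect, so the paired tumor-normal contrast
    of a panel gene estimates ``tumor_enrichment`` plus the prevalence-
    weighted cluster shift (exactly ``tumor_enrichment`` in a design with
    ``panel_shift`` 0).
    """
    bundle_rng = _rng_for(design, cohort_index, "normals")
    genes = design.gene_names()
    mu = _baselines(design)
    rng_expr = _rng_for(design, cohort_index, "expression")
    shift = pd.Series(
        rng_expr.normal(0.0, design.cohort_shift_sd, size=len(genes)) if cohort_index > 0 else 0.0,
        index=genes,
    )
    cohort_id = f"SYN{cohort_index:02d}"
    n = design.n_samples
    n_pairs = int(round(design.paired_fraction * n))
    donors = [f"{cohort_id}_D{i + 1:03d}" for i in range(n)][:n_pairs]
    if n_pairs == 0:
        empty = pd.DataFrame(index=genes)
        return ExpressionCohort(cohort_id=cohort_id, values=empty, sample_meta=pd.DataFrame())
    mean = mu.to_numpy()[:, None] + shift.to_numpy()[:, None]
    values = mean + bundle_rng.normal(0.0, design.noise_sd, size=(len(genes), n_pairs))
    samples = [d.replace("_D", "_N") for d in donors]
    meta = pd.DataFrame({"tissue": "normal", "donor_id": donors}, index=samples)
    return ExpressionCohort(
        cohort_id=cohort_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_meta=meta,
    )


def combine_tumor_normal(tumor: ExpressionCohort, normal: ExpressionCohort) -> ExpressionCohort:
    """Concatenate tumor and matched normal samples into one cohort."""
    if normal.n_samples == 0:
        return tumor
    values = pd.concat([tumor.values, normal.values], axis=1)
    meta = pd.concat([tumor.sample_meta, normal.sample_meta])
    return ExpressionCohort(cohort_id=tumor.cohort_id, values=values, sample_meta=meta)


def _censor_scale(rate_mix: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target censoring rate."""

    def frac_censored(c: float) -> float:
        # P(C < T) with T ~ Exp(h), C ~ U(0, c):  (1 - exp(-h c)) / (h c), averaged over h
        h = rate_mix
        return float(np.mean((1.0 - np.exp(-h * c)) / (h * c)))

    lo, hi = 1e-6, 1e9
    return brentq(lambda c: frac_censored(c) - target, lo, hi, maxiter=200)


def simulate_survival(
    design: SimulationDesign,
    cluster_labels: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Exponential survival with hazard h0 * exp(logHR * [cluster == high]).

    Independent Uniform(0, c) censoring with c tuned so the expected
    censoring fraction matches ``censoring_rate``.
    """
    if design.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be > 0")
    if design.censoring_rate >= 1.0:
        raise ValueError("censoring_rate 1.0 would censor every observation")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    z = (cluster_labels == "high").to_numpy().astype(int)
    rate = design.baseline_hazard * np.exp(design.cluster_log_hr * z)
    t_event = rng.exponential(1.0 / rate)
    if design.censoring_rate <= 0:
        time, event = t_event, np.ones_like(z)
    else:
        c = _censor_scale(rate, design.censoring_rate)
        t_cens = rng.uniform(0.0, c, size=z.size)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    idx = cluster_labels.index
    return pd.Series(time, index=idx, name="os_time"), pd.Series(event, index=idx, name="os_event")


# ---------------------------------------------------------------------------
# toy metabolic model

_TOY_REACTIONS: list[tuple[str, str, str]] = [
    # OXPHOS: complexes are AND chains over METAB genes, isoenzyme branches with OR
    ("OXPHOS_C1", "Oxidative phosphorylation", "METAB001 and METAB002 and METAB003"),
    ("OXPHOS_C3", "Oxidative phosphorylation", "(METAB004 and METAB005) or (METAB006 and METAB007)"),
    ("OXPHOS_C4", "Oxidative phosphorylation", "METAB008 and (METAB009 or METAB010)"),
    ("OXPHOS_ATP", "Oxidative phosphorylation", "METAB011 and METAB012"),
    ("TCA_CS", "Citric acid cycle", "METAB013"),
    ("TCA_IDH", "Citric acid cycle", "METAB014 or METAB015"),
    ("TCA_OGDH", "Citric acid cycle", "METAB016 and METAB017 and METAB018"),
    ("TCA_MDH", "Citric acid cycle", "METAB019 or (METAB020 and METAB021)"),
    ("FAO_CPT1", "Fatty acid oxidation", "METAB022 or METAB023"),
    ("FAO_ACAD", "Fatty acid oxidation", "METAB024 and METAB025"),
    ("FAO_HADH", "Fatty acid oxidation", "(METAB026 or METAB027) and METAB028"),
    ("FAO_KT", "Fatty acid oxidation", "METAB029"),
    ("TRP_IDO", "Tryptophan metabolism", "TRP001 or TRP002"),
    ("TRP_KYNU", "Tryptophan metabolism", "TRP003"),
    ("TRP_KMO", "Tryptophan metabolism", "TRP004 and TRP005"),
    ("TRP_HAAO", "Tryptophan metabolism", "TRP006 or (TRP007 and TRP008)"),
    # control reaction over unplanted genes: truly unregulated
    ("CTRL_NULL", "Control", "NULL0001 or NULL0002"),
    ("CTRL_NOGPR", "Control", ""),
]


def emit_toy_metabolic_model(design: SimulationDesign) -> tuple[MetabolicModelSpec, pd.Series]:
    """Toy Recon-style model over the simulated metabolic genes + true regulation.

    True regulation of a reaction is the exact GPR evaluation (AND = min,
    OR = sum) of the planted linear fold changes against an all-ones
    baseline, on the log2 scale; reactions without a GPR carry NaN.
    """
    genes = sorted({g for _, _, gpr in _TOY_REACTIONS if gpr for g in parse_gpr(gpr).gene_ids()})
    available = set(design.gene_names())
    missing = [g for g in genes if g not in available]
    if missing:
        raise ValueError(f"design too small for toy model: missing genes {missing}")
    reactions = [ReactionSpec(rid, gpr, subsystem) for rid, subsystem, gpr in _TOY_REACTIONS]
    model = MetabolicModelSpec(reactions=reactions, genes=genes)
    effects = design.gene_effects()
    fold = {g: float(2.0 ** effects.get(g, 0.0)) for g in genes}
    true = {}
    for r in reactions:
        if not r.has_gpr:
            true[r.reaction_id] = np.nan
            continue
        tree = parse_gpr(r.gpr)
        true[r.reaction_id] = float(np.log2(tree.evaluate(fold) / tree.evaluate({g: 1.0 for g in genes})))
    return model, pd.Series(true, name="true_log2_reg")


def simulate_study(design: SimulationDesign) -> list[CohortBundle]:
    """All cohorts of the design, tumors merged with their matched normals."""
    bundles = []
    for idx in range(design.n_cohorts):
        bundle = simulate_cohort(design, idx)
        normals = simulate_paired_normals(design, idx)
        bundle.cohort = combine_tumor_normal(bundle.cohort, normals)
        bundles.append(bundle)
    return bundles
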