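"""Ground-truth evaluation of the pipeline on the synthetic study design.

Each routine runs one pipeline stage against the generator's planted
truth under the default study conditions and returns summary operating
characteristics (recovery, coverage, error rates).  They are shared by
the test suite and by ``scripts/acceptance.py``.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children, so every routine is reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from . import clustering, screening, survival, synthetic
from .metabolic import estimate_reaction_regulation, summarize_subsystems
from .profiling import differential_expression
from .gpr import parse_gpr

__all__ = [
    "mc_calibration",
    "clustering_recovery",
    "projection_transfer",
    "screening_operating_characteristics",
    "peto_type1_error",
    "cox_hr_recovery",
    "ridge_concordance_gain",
    "pipeline_null_survival",
    "subsystem_regulation_recovery",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def mc_calibration(seed: int = 0, n_replicates: int = 30, n_draws: int = 1000) -> dict:
    """95% CI coverage of the Monte-Carlo reaction-regulation estimator.

    Per replicate, true gene log2 effects are drawn uniformly in [-1, 1]
    with standard errors in [0.05, 0.3]; the observed differential-
    expression estimate is true + N(0, SE).  Coverage counts, over all
    toy-model reactions with a GPR rule, how often the percentile CI
    brackets the exact GPR evaluation of the true effects.
    """
    design = synthetic.SimulationDesign(seed=seed)
    model, _ = synthetic.emit_toy_metabolic_model(design)
    rules = {r.reaction_id: parse_gpr(r.gpr) for r in model.reactions if r.has_gpr}
    covered = total = 0
    for rep_seed in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        true = pd.Series(rng.uniform(-1, 1, len(model.genes)), index=model.genes)
        se = pd.Series(rng.uniform(0.05, 0.3, len(model.genes)), index=model.genes)
        observed = true + rng.normal(0, se)
        contrasts = pd.DataFrame({"mean_diff": observed, "se": se})
        res = estimate_reaction_regulation(model, contrasts, n_draws=n_draws, seed=rep_seed)
        fold = {g: 2.0 ** true[g] for g in model.genes}
        ones = {g: 1.0 for g in model.genes}
        for rid, tree in rules.items():
            truth = np.log2(tree.evaluate(fold) / tree.evaluate(ones))
            row = res.table.loc[rid]
            covered += int(row["ci_low"] <= truth <= row["ci_high"])
            total += 1
    return {"coverage": covered / total, "n_reaction_replicates": total}


def clustering_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """PAM/cosine recovery of planted clusters and k-choice at default design."""
    aris, k_votes = [], 0
    for s in _child_seeds(seed, n_seeds):
        design = synthetic.SimulationDesign(seed=s, n_cohorts=1)
        bundle = synthetic.simulate_cohort(design, 0)
        scaled, _ = clustering.zscore_genes(bundle.cohort, list(design.chemokine_panel))
        model = clustering.pam_fit(scaled, k=2)
        aris.append(
            adjusted_rand_score(
                bundle.truth.cluster_labels.to_numpy(), model.assignments.to_numpy()
            )
        )
        diag = clustering.choose_k(scaled, range(2, 7))
        k_votes += int(diag.recommended_k == 2)
    return {
        "mean_ari": float(np.mean(aris)),
        "min_ari": float(np.min(aris)),
        "k2_votes": k_votes,
        "n_seeds": n_seeds,
    }


def projection_transfer(seed: int = 0) -> dict:
    """15-NN cross-cohort label transfer vs ground truth on a sibling cohort."""
    design = synthetic.SimulationDesign(seed=seed)
    train = synthetic.simulate_cohort(design, 0)
    test = synthetic.simulate_cohort(design, 1)
    model = clustering.fit_cluster_model(train.cohort, design.chemokine_panel, k=2)
    projected = clustering.knn_project(model, test.cohort, k_neighbors=15)
    truth = test.truth.cluster_labels
    agreement = float((projected.loc[truth.index] == truth).mean())
    scaled_train, _ = clustering.zscore_genes(train.cohort, list(design.chemokine_panel))
    scaled_test, _ = clustering.zscore_genes(test.cohort, list(design.chemokine_panel))
    ev_train = clustering.explained_variance(scaled_train, model.assignments)
    ev_test = clustering.explained_variance(scaled_test, projected)
    return {
        "agreement": agreement,
        "ev_train": ev_train,
        "ev_test": ev_test,
        "ev_gap": abs(ev_train - ev_test),
    }


def screening_operating_characteristics(
    seed: int = 0, n_seeds: int = 20, n_null_candidates: int = 50
) -> dict:
    """Sensitivity on the planted panel and selection rate of null genes."""
    hits = null_selected = null_total = 0
    for s in _child_seeds(seed, n_seeds):
        design = synthetic.SimulationDesign(seed=s, n_cohorts=1)
        bundle = synthetic.simulate_study(design)[0]
        nulls = [f"NULL{i:04d}" for i in range(1, n_null_candidates + 1)]
        res = screening.screen_chemokines(
            bundle.cohort, bundle.infiltration, list(design.chemokine_panel) + nulls
        )
        hits += len(set(res.selected) & set(design.chemokine_panel))
        null_selected += len([g for g in res.selected if g.startswith("NULL")])
        null_total += n_null_candidates
    n_panel = n_seeds * 8
    null_rate = null_selected / null_total
    return {
        "sensitivity": hits / n_panel,
        "null_selection_rate": null_rate,
        "null_mc_error": float(np.sqrt(max(null_rate, 1e-4) * (1 - null_rate) / null_total)),
        "n_seeds": n_seeds,
    }


def peto_type1_error(seed: int = 0, n_reps: int = 2000, n_per_arm: int = 100) -> dict:
    """Rejection rate of the Peto-Peto test at alpha=0.05 under the null."""
    design = synthetic.SimulationDesign(seed=seed, cluster_log_hr=0.0)
    labels = pd.Series(["high"] * n_per_arm + ["low"] * n_per_arm)
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        time, event = synthetic.simulate_survival(design, labels, rng=np.random.default_rng(s))
        _, p = survival.peto_peto_test(time, event, labels)
        rejections += int(p < 0.05)
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def cox_hr_recovery(
    seed: int = 0, n_reps: int = 20, n: int = 500, true_hr: float = 2.0
) -> dict:
    """Uni-variable Cox recovery of a planted per-unit hazard ratio."""
    in_band = 0
    hrs = []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        x = rng.normal(size=n)
        h = 0.001 * true_hr**x
        t_event = rng.exponential(1.0 / h)
        cens = rng.uniform(0, 3000, n)
        time = np.minimum(t_event, cens)
        event = (t_event <= cens).astype(int)
        res = survival.cox_univariable(time, event, x)
        hrs.append(res.hr)
        in_band += int(1.7 <= res.hr <= 2.35)
    return {"frac_in_band": in_band / n_reps, "median_hr": float(np.median(hrs)), "n_reps": n_reps}


def _survival_frame(rng, n, beta_clin, beta_genes):
    """Clinical covariates with planted effects plus an 8-gene expression block."""
    age = rng.normal(60, 10, n)
    grade = rng.integers(1, 5, n).astype(float)
    stage = rng.integers(1, 5, n).astype(float)
    genes = rng.normal(0, 1, size=(n, 8))
    lin = beta_clin[0] * (age - 60) / 10 + beta_clin[1] * grade + beta_clin[2] * stage
    lin = lin + genes @ np.full(8, beta_genes)
    t_event = rng.exponential(1.0 / (0.001 * np.exp(lin)))
    cens = rng.uniform(0, 4000, n)
    df = pd.DataFrame({"age": age, "grade": grade, "stage": stage})
    for j in range(8):
        df[f"gene{j}"] = genes[:, j]
    df["time"] = np.minimum(t_event, cens)
    df["event"] = (t_event <= cens).astype(int)
    return df


def ridge_concordance_gain(seed: int = 0, n: int = 400, beta_genes: float = 0.0) -> dict:
    """Added concordance of expression over clinical covariates in ridge Cox.

    With ``beta_genes`` 0 the expression block is pure noise, so the gain
    of the clinical+expression model over the clinical-only model on an
    independent validation cohort should vanish; a positive ``beta_genes``
    is the positive control.
    """
    s_train, s_val = _child_seeds(seed, 2)
    beta_clin = (0.4, 0.5, 0.6)
    train = _survival_frame(np.random.default_rng(s_train), n, beta_clin, beta_genes)
    val = _survival_frame(np.random.default_rng(s_val), n, beta_clin, beta_genes)
    clin_cols = ["age", "grade", "stage"]
    gene_cols = [f"gene{j}" for j in range(8)]
    m_clin = survival.ridge_cox(train, "time", "event", clin_cols, folds=5, seed=seed, validation=val)
    m_full = survival.ridge_cox(
        train, "time", "event", clin_cols + gene_cols, folds=5, seed=seed, validation=val
    )
    return {
        "c_clinical": m_clin.concordance,
        "c_full": m_full.concordance,
        "gain": m_full.concordance - m_clin.concordance,
    }


def pipeline_null_survival(
    seed: int = 0, n_reps: int = 200, n_samples: int = 120, n_genes: int = 110
) -> dict:
    """End-to-end null mirror: no cluster-survival association at default design.

    Each replicate simulates a cohort with a null survival effect,
    re-derives chemokine clusters with PAM from expression alone, and
    tests them against survival with Peto-Peto; the p-values should be
    uniform (Kolmogorov-Smirnov check).
    """
    ps = []
    for s in _child_seeds(seed, n_reps):
        design = synthetic.SimulationDesign(
            seed=s, n_samples=n_samples, n_genes=n_genes, n_cohorts=1, cluster_log_hr=0.0
        )
        bundle = synthetic.simulate_cohort(design, 0)
        scaled, _ = clustering.zscore_genes(bundle.cohort, list(design.chemokine_panel))
        model = clustering.pam_fit(scaled, k=2)
        meta = bundle.cohort.sample_meta
        _, p = survival.peto_peto_test(meta["os_time"], meta["os_event"], model.assignments)
        ps.append(p)
    ks = sps.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "median_p": float(np.median(ps)), "n_reps": n_reps}


def subsystem_regulation_recovery(seed: int = 0, n_draws: int = 1000) -> dict:
    """Full expression-to-metabolism run: planted module shifts at reaction level.

    Simulates a default cohort, recovers clusters with PAM, runs the
    genome-wide differential expression and the GPR Monte-Carlo step, and
    summarises the toy subsystems; reports the fractions of significantly
    inhibited oxidative reactions and activated tryptophan reactions.
    """
    design = synthetic.SimulationDesign(seed=seed, n_cohorts=1)
    bundle = synthetic.simulate_cohort(design, 0)
    scaled, _ = clustering.zscore_genes(bundle.cohort, list(design.chemokine_panel))
    model = clustering.pam_fit(scaled, k=2)
    de = differential_expression(bundle.cohort, model.assignments)
    toy, true_reg = synthetic.emit_toy_metabolic_model(design)
    res = estimate_reaction_regulation(toy, de, n_draws=n_draws, seed=seed)
    summary = summarize_subsystems(res.table)
    oxidative = ["Oxidative phosphorylation", "Citric acid cycle", "Fatty acid oxidation"]
    corr = float(
        np.corrcoef(res.table["log2_reg"], true_reg.loc[res.table.index])[0, 1]
    )
    return {
        "frac_inhibited_oxidative": float(summary.loc[oxidative, "frac_inhibited"].mean()),
        "frac_activated_trp": float(summary.loc["Tryptophan metabolism", "frac_activated"]),
        "regulation_truth_correlation": corr,
    }
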