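"""Survival analysis: Kaplan-Meier, Peto-Peto test, Cox models, concordance.

The Peto-Peto test is a weighted log-rank test whose weights are the
modified pooled survivor estimate S~(t) = prod_{t_i <= t} (1 - d_i/(n_i + 1)),
down-weighting late event times and hence sensitive to early hazard
differences.  Cox fits (uni-variable with a natural-cubic-spline term for
non-linearity, and ridge-penalised multi-parameter models) delegate to
lifelines; Harrell's concordance index compares clinical-only against
clinical-plus-expression risk models across cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "kaplan_meier",
    "peto_peto_test",
    "cox_univariable",
    "ridge_cox",
    "concordance_index",
    "CoxResult",
    "RidgeCoxModel",
]

logger = logging.getLogger(__name__)


def kaplan_meier(time, event) -> pd.DataFrame:
    """Product-limit survival estimate; frame with columns (time, survival).

    Right-continuous step function decreasing only at event times.  With
    no events the curve is flat at 1 (warning, not an error).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        logger.warning("no events: Kaplan-Meier curve is constant 1")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)})


def peto_peto_test(time, event, group, weights_one: bool = False) -> tuple[float, float]:
    """Two-group Peto-Peto weighted log-rank test; returns (chi2, p).

    ``weights_one`` forces all weights to 1, reducing the statistic to the
    standard log-rank test (used for oracle checks).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"need exactly two non-empty groups, found {labels.size}")
    if event.sum() == 0:
        raise ValueError("no events in either group")
    g1 = group == labels[0]
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    g1_sorted = g1[order]
    event_times = np.unique(t_sorted[e_sorted == 1])

    n = time.size
    chi_num = 0.0
    var_sum = 0.0
    s_tilde = 1.0
    for tj in event_times:
        at_risk = t_sorted >= tj
        nj = int(at_risk.sum())
        n1j = int((at_risk & g1_sorted).sum())
        dying = (t_sorted == tj) & (e_sorted == 1)
        dj = int(dying.sum())
        d1j = int((dying & g1_sorted).sum())
        s_tilde *= 1.0 - dj / (nj + 1.0)
        w = 1.0 if weights_one else s_tilde
        chi_num += w * (d1j - n1j * dj / nj)
        if nj > 1:
            var_sum += w**2 * dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var_sum == 0:
        return 0.0, 1.0
    chi2 = chi_num**2 / var_sum
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    """Uni-variable Cox fit for one covariate: linear HR plus spline non-linearity."""

    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    spline_p: float = np.nan
    converged: bool = True
    fdr: float = np.nan


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (df columns, first column = x itself).

    Knots sit at df+1 equally spaced quantiles of x; the remaining df-1
    columns are the standard truncated-power natural-spline functions,
    linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    K = df + 1
    knots = np.quantile(x, np.linspace(0, 1, K))
    knots = np.unique(knots)
    if knots.size < 3:
        raise ValueError("too few distinct knots for a spline basis")

    def d(k):
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    for k in range(len(knots) - 2):
        cols.append(d(k) - d(len(knots) - 2))
    return np.column_stack(cols)


def cox_univariable(time, event, covariate, term: str = "x", spline_df: int = 3) -> CoxResult:
    """Cox PH fit with a linear plus natural-cubic-spline term.

    The hazard ratio is reported for the linear term per unit covariate,
    taken from the linear-only fit where it is identified (the spline
    columns are strongly collinear with the covariate); ``spline_p`` is
    the likelihood-ratio test of the spline (non-linear) terms against
    that linear-only model.  Non-convergence is flagged on the result
    instead of raised.
    """
    covariate = np.asarray(covariate, dtype=float)
    if np.ptp(covariate) == 0:
        raise ValueError("constant covariate")
    if int(np.asarray(event).sum()) < 10:
        raise ValueError("need >= 10 events for a stable Cox fit")
    basis = natural_spline_basis(covariate, df=spline_df)
    cols = ["lin"] + [f"s{i}" for i in range(1, basis.shape[1])]
    df_full = pd.DataFrame(basis, columns=cols)
    df_full["time"] = np.asarray(time, dtype=float)
    df_full["event"] = np.asarray(event, dtype=int)
    try:
        full = CoxPHFitter().fit(df_full, "time", "event")
        lin = CoxPHFitter().fit(df_full[["lin", "time", "event"]], "time", "event")
    except Exception as exc:  # noqa: BLE001 - flagged, not raised
        logger.warning("Cox fit for %s failed to converge: %s", term, exc)
        return CoxResult(term=term, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                         p=np.nan, spline_p=np.nan, converged=False)
    lr = 2.0 * (full.log_likelihood_ - lin.log_likelihood_)
    spline_p = float(sps.chi2.sf(max(lr, 0.0), df=len(cols) - 1))
    hr = float(np.exp(lin.params_["lin"]))
    ci = lin.confidence_intervals_.loc["lin"].to_numpy(float)
    return CoxResult(
        term=term, hr=hr, ci_low=float(np.exp(ci[0])), ci_high=float(np.exp(ci[1])),
        p=float(lin.summary.loc["lin", "p"]), spline_p=spline_p,
    )


def cox_univariable_panel(data: pd.DataFrame, time_col: str, event_col: str,
                          covariates: list[str], spline_df: int = 3) -> pd.DataFrame:
    """Per-gene uni-variable Cox fits with FDR across genes."""
    results = [
        cox_univariable(data[time_col], data[event_col], data[c], term=c, spline_df=spline_df)
        for c in covariates
    ]
    table = pd.DataFrame(
        [{"term": r.term, "hr": r.hr, "ci_low": r.ci_low, "ci_high": r.ci_high,
          "p": r.p, "spline_p": r.spline_p, "converged": r.converged} for r in results]
    ).set_index("term")
    ok = table["p"].notna()
    table.loc[ok, "fdr"] = bh_fdr(table.loc[ok, "p"].to_numpy())
    return table


@dataclass
class RidgeCoxModel:
    coefficients: pd.Series
    penalizer: float
    cv_path: pd.DataFrame = field(default_factory=pd.DataFrame)
    concordance: float = np.nan
    dropped: list[str] = field(default_factory=list)


def _stratified_event_folds(event: np.ndarray, folds: int, seed: int | None) -> np.ndarray:
    """Fold ids balanced over event status."""
    rng = np.random.default_rng(seed)
    fold_id = np.empty(event.size, dtype=int)
    for status in (0, 1):
        idx = np.flatnonzero(event == status)
        rng.shuffle(idx)
        fold_id[idx] = np.arange(idx.size) % folds
    return fold_id


def ridge_cox(
    data: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates: list[str],
    lambdas=(0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
    folds: int = 5,
    seed: int | None = 0,
    validation: pd.DataFrame | None = None,
) -> RidgeCoxModel:
    """L2-penalised Cox regression with cross-validated penalty choice.

    Covariates are standardised internally (zero-variance columns dropped
    with a warning); the penalty maximises the cross-validated partial
    log-likelihood over ``lambdas`` with folds stratified by event status.
    Harrell's concordance is evaluated on ``validation`` (or the training
    data when none is given).
    """
    event = data[event_col].to_numpy(int)
    if event.sum() < 20:
        raise ValueError("need >= 20 events for ridge Cox")
    kept, dropped = [], []
    for c in covariates:
        if np.ptp(data[c].to_numpy(float)) == 0:
            dropped.append(c)
            logger.warning("dropping zero-variance covariate %r", c)
        else:
            kept.append(c)
    mean = data[kept].mean()
    sd = data[kept].std(ddof=1)

    def design(frame: pd.DataFrame) -> pd.DataFrame:
        out = (frame[kept] - mean) / sd
        out[time_col] = frame[time_col].to_numpy(float)
        out[event_col] = frame[event_col].to_numpy(int)
        return out

    train = design(data)
    fold_id = _stratified_event_folds(event, folds, seed)
    path = []
    for lam in lambdas:
        lls = []
        for f in range(folds):
            tr, te = train[fold_id != f], train[fold_id == f]
            try:
                fit = CoxPHFitter(penalizer=lam, l1_ratio=0.0).fit(tr, time_col, event_col)
                lls.append(fit.score(te, scoring_method="log_likelihood"))
            except Exception as exc:  # noqa: BLE001
                logger.warning("fold %d at lambda=%g failed: %s", f, lam, exc)
        path.append({"lambda": lam, "cv_log_likelihood": float(np.mean(lls)) if lls else -np.inf})
    cv_path = pd.DataFrame(path)
    lam_opt = float(cv_path.loc[cv_path["cv_log_likelihood"].idxmax(), "lambda"])
    final = CoxPHFitter(penalizer=lam_opt, l1_ratio=0.0).fit(train, time_col, event_col)
    coef = final.params_.copy()
    val = design(validation) if validation is not None else train
    risk = val[kept].to_numpy(float) @ coef.reindex(kept).to_numpy(float)
    c_index = concordance_index(risk, val[time_col].to_numpy(), val[event_col].to_numpy())
    return RidgeCoxModel(coefficients=coef, penalizer=lam_opt, cv_path=cv_path,
                         concordance=c_index, dropped=dropped)


def concordance_index(risk_scores, time, event) -> float:
    """Harrell's C for risk scores (higher risk = earlier event expected).

    Ties in risk count 0.5; censored-censored pairs are unusable.
    Invariant to monotone transforms of the scores.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no usable pairs: no events")
    return float(_lifelines_cindex(time, -np.asarray(risk_scores, dtype=float), event))
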