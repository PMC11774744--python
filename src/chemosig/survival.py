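"""Prognostic labelling, Kaplan-Meier / log-rank, and Cox PH evaluation.

The 5-year dichotomization: an event within the horizon is unfavorable; a
patient who reached the horizon event-free is favorable; an event-free
patient censored before the horizon is uncertain and is excluded from
classifier training/testing but kept (as censored) in complete-cohort
survival analyses.

Kaplan-Meier and the log-rank test are delegated to lifelines. The Cox
model is fit here by Newton-Raphson on the partial likelihood, with both
Efron (default) and Breslow handling of tied event times, because the
surrounding ecosystem exposes only one tie convention with standard
errors. Hazard ratios are exp(beta) with 95% Wald intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .datamodel import (CohortTable, FAVORABLE, UNCERTAIN, UNFAVORABLE,
                        ExpressionMatrix)


# ---------------------------------------------------------------------------
# prognostic status

def define_prognostic_status(cohort: CohortTable, horizon: float = 5.0,
                             endpoint: str = "OS") -> np.ndarray:
    """5-year (by default) favorable/unfavorable/uncertain labels.

    ``endpoint`` is a tag only (OS vs RFS); the rule is identical: the
    event indicator is interpreted as death (OS) or relapse (RFS).
    """
    if endpoint not in ("OS", "RFS"):
        raise ValueError("endpoint must be 'OS' or 'RFS'")
    t = cohort.time_years
    e = cohort.event
    if np.any(t < 0):
        raise ValueError("negative survival time")
    status = np.empty(len(t), dtype=object)
    unfav = (e == 1) & (t <= horizon)
    fav = ~unfav & (t >= horizon)
    status[unfav] = UNFAVORABLE
    status[fav] = FAVORABLE
    status[~unfav & ~fav] = UNCERTAIN
    return status


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank

@dataclass
class SurvivalCurve:
    group: str
    event_times: np.ndarray      # distinct times with >= 1 event
    survival: np.ndarray         # product-limit estimate just after each time
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimates must be non-increasing")


def kaplan_meier(times, events, groups=None) -> Dict[str, SurvivalCurve]:
    """Product-limit curve per group (single group "all" when None)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups is None:
        groups = np.array(["all"] * len(times), dtype=object)
    groups = np.asarray(groups, dtype=object)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table[kmf.event_table["observed"] > 0]
        et = tab.index.to_numpy(dtype=float)
        surv = kmf.survival_function_at_times(et).to_numpy()
        out[str(g)] = SurvivalCurve(group=str(g), event_times=et,
                                    survival=surv,
                                    at_risk=tab["at_risk"].to_numpy(),
                                    events=tab["observed"].to_numpy())
    return out


def logrank_test(times, events, groups):
    """Log-rank chi-square across >= 2 groups; returns (stat, p, df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=object)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    if events.sum() == 0:
        raise ValueError("log-rank test undefined with no events")
    res = multivariate_logrank_test(times, groups, events)
    df = len(labels) - 1
    return float(res.test_statistic), float(res.p_value), int(df)


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass
class CoxResult:
    table: pd.DataFrame          # covariate, coef, hazard_ratio, ci_lower, ci_upper, p
    log_likelihood: float
    ties_method: str
    converged: bool
    monotone_likelihood: bool = False

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.set_index("covariate").loc[covariate, "hazard_ratio"])


def cox_log_partial_likelihood(beta, times, events, X, ties: str = "efron") -> float:
    """Log partial likelihood at ``beta`` (exposed for closed-form checks)."""
    ll, _, _ = _cox_ll_grad_hess(np.asarray(beta, dtype=float),
                                 *_cox_prepare(times, events, X), ties)
    return float(ll)


def _cox_prepare(times, events, X):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(times, kind="stable")
    return times[order], events[order], X[order]


def _cox_ll_grad_hess(beta, t, e, X, ties):
    """One pass over event times with suffix cumulative sums."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # rescale for stability; cancels in ratios
    w = np.exp(eta)
    wx = X * w[:, None]
    # suffix sums: risk set of time t_i = samples with t >= t_i
    S0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    S1 = np.vstack([np.cumsum(wx[::-1], axis=0)[::-1], np.zeros(p)])
    # second moments per sample, suffix-summed
    xxw = np.einsum("ij,ik->ijk", X, wx)
    S2 = np.concatenate([np.cumsum(xxw[::-1], axis=0)[::-1],
                         np.zeros((1, p, p))])
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dead = np.flatnonzero(e[i:j] == 1) + i
        d = dead.size
        if d > 0:
            s0 = S0[i]
            s1 = S1[i]
            s2 = S2[i]
            ll += eta[dead].sum()
            if ties == "breslow":
                ll -= d * np.log(s0)
                grad += X[dead].sum(axis=0) - d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1, s1) / s0 ** 2)
            elif ties == "efron":
                wd = w[dead].sum()
                wxd = wx[dead].sum(axis=0)
                xxd = xxw[dead].sum(axis=0)
                grad += X[dead].sum(axis=0)
                for l in range(d):
                    f = l / d
                    d0 = s0 - f * wd
                    d1 = s1 - f * wxd
                    d2 = s2 - f * xxd
                    ll -= np.log(d0)
                    grad -= d1 / d0
                    hess -= d2 / d0 - np.outer(d1, d1) / d0 ** 2
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j
    return ll, grad, hess


def cox_ph(times, events, covariates, ties: str = "efron") -> CoxResult:
    """Multivariate Cox PH fit (Newton-Raphson on the partial likelihood).

    ``covariates`` is a DataFrame (or array) of numeric / one-hot columns.
    Constant columns raise a singularity error naming them; monotone
    likelihood (e.g. a level containing all events) is flagged, not raised.
    """
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    if isinstance(covariates, pd.DataFrame):
        non_num = [c for c in covariates.columns
                   if not np.issubdtype(covariates[c].dtype, np.number)]
        if non_num:
            raise ValueError(f"non-numeric covariates (one-hot encode them): {non_num}")
        names = list(covariates.columns)
        Xraw = covariates.to_numpy(dtype=float)
    else:
        Xraw = np.asarray(covariates, dtype=float)
        if Xraw.ndim == 1:
            Xraw = Xraw[:, None]
        names = [f"x{i}" for i in range(Xraw.shape[1])]
    const = [names[j] for j in range(Xraw.shape[1])
             if np.ptp(Xraw[:, j]) == 0]
    if const:
        raise ValueError(f"singular design: constant covariate(s) {', '.join(const)}")
    events_arr = np.asarray(events, dtype=int)
    if events_arr.sum() == 0:
        raise ValueError("no events; Cox model undefined")

    t, e, X = _cox_prepare(times, events_arr, Xraw)
    # standardize internally for numerical stability, back-transform after
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Xs = (X - mu) / sd
    p = X.shape[1]
    if np.linalg.matrix_rank(Xs) < p:
        raise ValueError("singular design: collinear covariates "
                         f"among {', '.join(names)}")
    beta = np.zeros(p)
    converged = False
    monotone = False
    for _ in range(60):
        ll, grad, hess = _cox_ll_grad_hess(beta, t, e, Xs, ties)
        try:
            step = np.linalg.solve(-hess + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            raise ValueError("singular information matrix in Cox fit")
        # step-halving
        new = beta + step
        for _h in range(25):
            ll_new, _, _ = _cox_ll_grad_hess(new, t, e, Xs, ties)
            if ll_new >= ll - 1e-12:
                break
            new = beta + (new - beta) * 0.5
        beta = new
        if np.max(np.abs(step)) < 1e-9:
            converged = True
            break
    # > 10 log-hazard units per covariate SD: coefficient is running away
    if np.max(np.abs(beta)) > 10:
        monotone = True
        converged = False
    ll, grad, hess = _cox_ll_grad_hess(beta, t, e, Xs, ties)
    cov_s = np.linalg.inv(-hess + 1e-12 * np.eye(p))
    # back-transform to original covariate scale
    coef = beta / sd
    se = np.sqrt(np.diag(cov_s)) / sd
    from scipy import stats as sps
    z = coef / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        hr = np.exp(coef)
    with np.errstate(over="ignore"):
        table = pd.DataFrame({
            "covariate": names,
            "coef": coef,
            "se": se,
            "hazard_ratio": hr,
            "ci_lower": np.exp(coef - 1.959963984540054 * se),
            "ci_upper": np.exp(coef + 1.959963984540054 * se),
            "p": pvals,
        })
    return CoxResult(table=table, log_likelihood=float(ll), ties_method=ties,
                     converged=converged, monotone_likelihood=monotone)


# ---------------------------------------------------------------------------
# end-to-end evaluation of predicted groups

def evaluate_predictions(cohort: CohortTable, labels, covariates=None) -> dict:
    """KM + log-rank + multivariate Cox for classifier-predicted groups.

    ``labels`` are per-patient predicted statuses aligned with
    ``cohort.sample_ids`` (uncertain-status patients included, censored at
    last follow-up). The Cox design is predicted status (unfavorable=1)
    plus any supplied clinical covariates.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape != (cohort.n_patients,):
        raise ValueError("labels must cover the whole cohort")
    report: dict = {"n": cohort.n_patients}
    curves = kaplan_meier(cohort.time_years, cohort.event, labels)
    report["km"] = curves
    if len(set(labels)) < 2:
        warnings.warn("single predicted group; log-rank and Cox skipped")
        report["degenerate_grouping"] = True
        return report
    stat, pval, df = logrank_test(cohort.time_years, cohort.event, labels)
    report["logrank"] = {"statistic": stat, "p": pval, "df": df}
    design = pd.DataFrame(
        {"predicted_unfavorable": (labels == UNFAVORABLE).astype(float)},
        index=cohort.sample_ids)
    if covariates is not None:
        design = pd.concat([design, pd.DataFrame(covariates, index=cohort.sample_ids)],
                           axis=1)
    report["cox"] = cox_ph(cohort.time_years, cohort.event, design)
    return report
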