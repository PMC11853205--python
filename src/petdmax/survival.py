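"""Survival workflow statistics.

Cox proportional-hazards regression (univariate and forward-stepwise with
backward elimination), ROC-based Youden-optimal cutoff selection,
Kaplan-Meier estimation and log-rank tests, and the three-group
dissemination x tumor-burden stratification.

The Cox partial likelihood is maximized by Newton iterations with the Efron
tie correction by default (Breslow available); per-variable Wald statistics
and the model likelihood-ratio chi-square are reported.  Kaplan-Meier
curves and the log-rank chi-square are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "CoxResult",
    "CutoffResult",
    "LogRankResult",
    "cox_fit",
    "cox_stepwise",
    "roc_best_cutoff",
    "km_logrank",
    "stratify_dmax_mtv",
    "outcome_columns",
]

logger = logging.getLogger(__name__)

STRATUM_LABELS = ("both_low", "one_high", "both_high")


def outcome_columns(outcome: str) -> tuple[str, str]:
    """Map an outcome name ("OS" or "PFS") to its (time, event) columns."""
    key = outcome.lower()
    if key not in ("os", "pfs"):
        raise ValueError(f"outcome must be 'OS' or 'PFS', got {outcome!r}")
    return f"{key}_months", f"{key}_event"


@dataclass(frozen=True)
class CoxResult:
    """A fitted Cox proportional-hazards model."""

    variables: tuple[str, ...]
    coef: np.ndarray                  # log hazard per unit
    hazard_ratio: np.ndarray          # exp(coef)
    se: np.ndarray
    wald_chi2: np.ndarray
    wald_p: np.ndarray
    model_chi2: float                 # likelihood-ratio statistic vs null
    model_p: float
    log_likelihood: float
    null_log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"
    inclusion_log: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "HR": self.hazard_ratio, "se": self.se,
            "wald_chi2": self.wald_chi2, "p": self.wald_p,
        }, index=list(self.variables))


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal dichotomization cutoff for one variable."""

    variable: str
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class LogRankResult:
    """Log-rank comparison of Kaplan-Meier curves across groups."""

    group_labels: tuple
    chi_square: float
    df: int
    p: float
    group_n: dict
    group_events: dict
    curves: dict  # label -> (times, survival probabilities), step coordinates


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def cox_partial_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                       event: np.ndarray, ties: str = "efron"):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Risk sets are {j : t_j >= t}; tied event times are handled by the Efron
    or Breslow approximation.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    eta = X @ beta
    # shift guards exp overflow; every death contributes matched eta and log
    # terms, so the partial log-likelihood is unchanged by the shift
    if n:
        eta = eta - eta.max()
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # reverse cumulative risk-set sums
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    if n and np.unique(time).size == n:
        # all times distinct: tie corrections vanish, fully vectorized
        ev = event.astype(bool)
        ll = float(eta[ev].sum() - np.log(S0[ev]).sum())
        ratios = S1[ev] / S0[ev, None]
        grad = X[ev].sum(axis=0) - ratios.sum(axis=0)
        hess = -(S2[ev] / S0[ev, None, None]).sum(axis=0) + ratios.T @ ratios
        return ll, grad, hess

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = np.nonzero(event[i:j])[0] + i
        d = deaths.size
        if d:
            ll += float(eta[deaths].sum())
            grad += X[deaths].sum(axis=0)
            s0, s1, s2 = S0[i], S1[i], S2[i]
            if ties == "breslow" or d == 1:
                for _ in range(d):
                    ll -= np.log(s0)
                    grad -= s1 / s0
                    hess -= s2 / s0 - np.outer(s1, s1) / s0 ** 2
            elif ties == "efron":
                wd = float(w[deaths].sum())
                s1d = wx[deaths].sum(axis=0)
                s2d = wxx[deaths].sum(axis=0)
                for l in range(d):
                    f = l / d
                    phi0 = s0 - f * wd
                    phi1 = s1 - f * s1d
                    phi2 = s2 - f * s2d
                    ll -= np.log(phi0)
                    grad -= phi1 / phi0
                    hess -= phi2 / phi0 - np.outer(phi1, phi1) / phi0 ** 2
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return ll, grad, hess


class SeparationError(RuntimeError):
    """Monotone partial likelihood: a covariate perfectly separates risk."""


def _newton_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                variables: Sequence[str], ties: str,
                tol: float = 1e-9, max_iter: int = 60):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = cox_partial_loglik(beta, X, time, event, ties)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix; check for a perfectly "
                f"separating or constant covariate among {list(variables)}")
        new_beta = beta + step
        new_ll, new_grad, new_hess = cox_partial_loglik(new_beta, X, time, event, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = cox_partial_loglik(new_beta, X, time, event, ties)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 50:
            worst = variables[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"monotone partial likelihood: covariate {worst!r} appears to "
                "perfectly separate event risk (coefficient diverges)")
    else:
        worst = variables[int(np.argmax(np.abs(beta)))]
        raise SeparationError(
            f"Cox fit did not converge; covariate {worst!r} has the most "
            "extreme coefficient (possible monotone likelihood)")
    if np.max(np.abs(beta)) > 8:
        # plateau check: a monotone likelihood flattens out as |beta| grows
        # (weight underflow at the probe point is the same pathology)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ll2, _, _ = cox_partial_loglik(2 * beta, X, time, event, ties)
        if not np.isfinite(ll2) or abs(ll2 - ll) < 1e-2:
            worst = variables[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"monotone partial likelihood: covariate {worst!r} appears to "
                "perfectly separate event risk (likelihood has no interior "
                "maximum)")
    return beta, ll, grad, hess


def _prepare(cohort: pd.DataFrame, outcome: str, variables: Sequence[str]):
    time_col, event_col = outcome_columns(outcome)
    cols = [time_col, event_col, *variables]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks column(s) {missing}")
    sub = cohort[cols].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("cox_fit(%s): excluded %d row(s) with missing values",
                    outcome, dropped)
    time = complete[time_col].to_numpy(dtype=float)
    event = complete[event_col].to_numpy(dtype=float)
    if np.any(time < 0):
        raise ValueError("survival times must be non-negative")
    if not np.all(np.isin(event, (0.0, 1.0))):
        raise ValueError("event flags must be 0/1")
    X = complete[list(variables)].to_numpy(dtype=float)
    return X, time, event.astype(int)


def cox_fit(cohort: pd.DataFrame, outcome: str, variables: Sequence[str],
            ties: str = "efron") -> CoxResult:
    """Fit a Cox proportional-hazards model.

    ``variables`` must be numeric columns (categoricals pre-coded).  Rows
    with missing values in any used column are excluded with a logged count.
    Raises :class:`SeparationError` for a perfectly separating covariate.
    """
    variables = list(variables)
    X, time, event = _prepare(cohort, outcome, variables)
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError(f"no events observed for outcome {outcome}")
    ll0, _, _ = cox_partial_loglik(np.zeros(X.shape[1]), X, time, event, ties)
    if not variables:
        return CoxResult(variables=(), coef=np.zeros(0), hazard_ratio=np.zeros(0),
                         se=np.zeros(0), wald_chi2=np.zeros(0), wald_p=np.zeros(0),
                         model_chi2=0.0, model_p=1.0, log_likelihood=ll0,
                         null_log_likelihood=ll0, n=len(time), n_events=n_events,
                         ties=ties)
    beta, ll, _, hess = _newton_cox(X, time, event, variables, ties)
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        raise SeparationError(
            "singular information matrix at the optimum; check for collinear "
            f"covariates among {variables}")
    se = np.sqrt(np.diag(cov))
    wald_chi2 = (beta / se) ** 2
    wald_p = stats.chi2.sf(wald_chi2, df=1)
    model_chi2 = max(2.0 * (ll - ll0), 0.0)
    model_p = float(stats.chi2.sf(model_chi2, df=len(variables)))
    return CoxResult(
        variables=tuple(variables), coef=beta, hazard_ratio=np.exp(beta),
        se=se, wald_chi2=wald_chi2, wald_p=wald_p,
        model_chi2=float(model_chi2), model_p=model_p,
        log_likelihood=float(ll), null_log_likelihood=float(ll0),
        n=len(time), n_events=n_events, ties=ties)


def cox_stepwise(cohort: pd.DataFrame, outcome: str, candidates: Sequence[str],
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 ties: str = "efron") -> CoxResult:
    """Forward-stepwise Cox selection with backward checks.

    Repeatedly adds the candidate with the smallest likelihood-ratio p-value
    below ``p_enter``, then removes any included variable whose removal LR
    p-value exceeds ``p_remove``.  Visited models are tracked so the
    procedure terminates without add/remove oscillation.  Returns the final
    fit (possibly the empty model) with an inclusion log.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("at least one candidate variable is required")
    included: list[str] = []
    log: list[str] = []
    seen = {frozenset()}

    def lr_p(bigger: list[str], smaller: list[str]) -> float:
        fb = cox_fit(cohort, outcome, bigger, ties)
        fs = cox_fit(cohort, outcome, smaller, ties)
        chi2 = max(2.0 * (fb.log_likelihood - fs.log_likelihood), 0.0)
        return float(stats.chi2.sf(chi2, df=len(bigger) - len(smaller)))

    while True:
        changed = False
        # forward step
        best_var, best_p = None, np.inf
        for var in candidates:
            if var in included:
                continue
            try:
                p_val = lr_p(included + [var], included)
            except SeparationError:
                continue
            if p_val < best_p:
                best_var, best_p = var, p_val
        if best_var is not None and best_p < p_enter:
            trial = frozenset(included) | {best_var}
            if trial not in seen:
                included.append(best_var)
                seen.add(trial)
                log.append(f"add {best_var} (LR p={best_p:.4g})")
                changed = True
        # backward step
        worst_var, worst_p = None, -np.inf
        for var in included:
            rest = [v for v in included if v != var]
            p_val = lr_p(included, rest)
            if p_val > worst_p:
                worst_var, worst_p = var, p_val
        if worst_var is not None and worst_p > p_remove:
            trial = frozenset(included) - {worst_var}
            if trial not in seen:
                included.remove(worst_var)
                seen.add(trial)
                log.append(f"remove {worst_var} (LR p={worst_p:.4g})")
                changed = True
        if not changed:
            break

    fit = cox_fit(cohort, outcome, included, ties)
    return CoxResult(**{**fit.__dict__, "inclusion_log": tuple(log)})


# ---------------------------------------------------------------------------
# ROC cutoff, Kaplan-Meier / log-rank, stratification
# ---------------------------------------------------------------------------

def roc_best_cutoff(cohort: pd.DataFrame, variable: str,
                    outcome: str = "OS") -> CutoffResult:
    """Youden-optimal dichotomization cutoff for a continuous marker.

    The positive class is the outcome event flag at end of follow-up
    (died / progressed); a patient is test-positive when the marker exceeds
    the cutoff.  Candidate cutoffs are the midpoints between consecutive
    distinct observed values; exact ties in Youden J are broken toward the
    lower cutoff.
    """
    _, event_col = outcome_columns(outcome)
    sub = cohort[[variable, event_col]].dropna()
    values = sub[variable].to_numpy(dtype=float)
    labels = sub[event_col].to_numpy(dtype=float)
    pos, neg = values[labels == 1], values[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"ROC cutoff for {variable!r} requires both outcome classes "
            f"(events={pos.size}, non-events={neg.size})")
    distinct = np.unique(values)
    if distinct.size < 2:
        return CutoffResult(variable, float(distinct[0]), 0.0, 1.0, 0.0)
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for cut in cuts:
        sens = float(np.mean(pos > cut))
        spec = float(np.mean(neg <= cut))
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(variable, float(cut), sens, spec, j)
    return best


def km_logrank(cohort: pd.DataFrame, outcome: str,
               grouping: Sequence) -> LogRankResult:
    """Kaplan-Meier curves per group plus the log-rank chi-square test.

    ``grouping`` is a label per cohort row; df = n_groups - 1.
    """
    time_col, event_col = outcome_columns(outcome)
    groups = pd.Series(np.asarray(grouping, dtype=object), index=cohort.index)
    sub = pd.DataFrame({
        "time": pd.to_numeric(cohort[time_col]),
        "event": pd.to_numeric(cohort[event_col]),
        "group": groups,
    }).dropna()
    labels = sorted(sub["group"].unique(), key=str)
    if len(labels) < 2:
        raise ValueError(f"log-rank needs >= 2 non-empty groups, got {len(labels)}")
    if sub["event"].sum() == 0:
        raise ValueError("log-rank undefined: all observations censored")
    res = multivariate_logrank_test(sub["time"], sub["group"], sub["event"])
    curves, group_n, group_events = {}, {}, {}
    for lab in labels:
        g = sub[sub["group"] == lab]
        kmf = KaplanMeierFitter()
        kmf.fit(g["time"], event_observed=g["event"])
        sf = kmf.survival_function_
        curves[lab] = (sf.index.to_numpy(dtype=float),
                       sf.iloc[:, 0].to_numpy(dtype=float))
        group_n[lab] = int(len(g))
        group_events[lab] = int(g["event"].sum())
    return LogRankResult(
        group_labels=tuple(labels),
        chi_square=float(res.test_statistic),
        df=len(labels) - 1,
        p=float(res.p_value),
        group_n=group_n, group_events=group_events, curves=curves)


def stratify_dmax_mtv(cohort: pd.DataFrame, dmax_cut: float, mtv_cut: float,
                      dmax_col: str = "dmax_cm",
                      mtv_col: str = "mtv_tot_ml") -> pd.Series:
    """Three-group stratification by dissemination and total tumor burden.

    Groups: both markers <= their cutoffs ("both_low"), exactly one above
    ("one_high"), both above ("both_high").  Values equal to a cutoff count
    as below-or-equal.
    """
    for col in (dmax_col, mtv_col):
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks column {col!r}")
    n_above = ((cohort[dmax_col] > dmax_cut).astype(int)
               + (cohort[mtv_col] > mtv_cut).astype(int))
    return n_above.map(dict(enumerate(STRATUM_LABELS))).rename("dmax_mtv_group")
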