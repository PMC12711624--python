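"""Survival analysis: Kaplan-Meier curves, log-rank tests and Cox models.

Thin, typed wrappers around lifelines (product-limit estimator, two-group
log-rank, Efron-tie Cox partial likelihood) returning plain containers that
the pipeline serialises. Separation / non-convergence in the Cox fit is
detected and reported as a flag rather than raised, since small validation
cohorts routinely produce monotone likelihoods for some covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import ConvergenceWarning

log = logging.getLogger(__name__)


@dataclass
class KMCurve:
    group_label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class SurvivalFit:
    """Cox proportional-hazards fit summary (per-covariate arrays)."""

    covariates: list[str]
    coefficients: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray          # n_covariates x 2, on the HR scale
    wald_p: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    message: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hr,
                "HR_lo95": self.ci95[:, 0],
                "HR_hi95": self.ci95[:, 1],
                "p": self.wald_p,
            },
            index=self.covariates,
        )


def _check_time_event(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if (time <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


def km_estimate(time, event, groups=None) -> dict[str, KMCurve]:
    """Product-limit survival curve per group (single group if None)."""
    time, event = _check_time_event(time, event)
    groups = np.asarray(["all"] * time.size if groups is None else groups)
    curves: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        tgrid = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = np.array([np.sum(time[sel] >= t) for t in tgrid])
        curves[str(g)] = KMCurve(str(g), tgrid, surv, at_risk)
    return curves


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    time, event = _check_time_event(time, event)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    a, b = (group == levels[0]), (group == levels[1])
    if event.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    res = _ll_logrank(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
    return float(res.test_statistic), float(res.p_value)


def drop_zero_event_strata(df: pd.DataFrame, stratum_col: str, event_col: str = "event") -> pd.DataFrame:
    """Remove strata in which no event occurred (logged, never silent).

    Guards a multivariable Cox fit against complete separation from
    event-free subgroups (e.g. early-stage patients with no deaths).
    """
    counts = df.groupby(stratum_col, observed=True)[event_col].sum()
    dead = counts[counts == 0].index.tolist()
    if dead:
        n_before = len(df)
        df = df[~df[stratum_col].isin(dead)]
        log.warning(
            "dropped %d samples in zero-event %s strata %s before Cox fit",
            n_before - len(df), stratum_col, dead,
        )
    return df


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    ties: str = "efron",
    ridge: float = 0.0,
) -> SurvivalFit:
    """Cox proportional-hazards regression (Efron ties by default).

    Maximises the partial likelihood by Newton-Raphson with step-halving;
    Wald 95% CIs are exp(beta +/- 1.96 SE). Separation or non-convergence
    yields ``converged=False`` with NaN estimates where undefined instead
    of an exception. ``ridge`` adds an optional small L2 penalty as a
    separation rescue (off by default).
    """
    if ties != "efron":
        raise NotImplementedError("only Efron tie handling is implemented")
    time, event = _check_time_event(time, event)
    cov = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
    constant = [c for c in cov.columns if cov[c].nunique(dropna=True) <= 1]
    if constant:
        raise ValueError(f"constant covariates {constant} cannot enter a Cox model")
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("Cox model needs at least one event")
    if n_events < cov.shape[1]:
        log.warning("Cox fit: %d events for %d covariates; estimates may be unstable", n_events, cov.shape[1])

    df = cov.copy()
    df["time"], df["event"] = time, event
    cph = CoxPHFitter(penalizer=ridge)
    converged, message = True, ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as err:
            return SurvivalFit(
                covariates=list(cov.columns),
                coefficients=np.full(cov.shape[1], np.nan),
                hr=np.full(cov.shape[1], np.nan),
                ci95=np.full((cov.shape[1], 2), np.nan),
                wald_p=np.full(cov.shape[1], np.nan),
                loglik=np.nan,
                n=len(df),
                n_events=n_events,
                converged=False,
                message=str(err),
            )
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                converged = False
                message = str(w.message)
                log.warning("Cox fit flagged: %s", message)

    s = cph.summary
    return SurvivalFit(
        covariates=list(s.index),
        coefficients=s["coef"].to_numpy(),
        hr=s["exp(coef)"].to_numpy(),
        ci95=s[["exp(coef) lower 95%", "exp(coef) upper 95%"]].to_numpy(),
        wald_p=s["p"].to_numpy(),
        loglik=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        converged=converged,
        message=message,
    )
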