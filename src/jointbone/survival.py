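"""Survival kernels: Kaplan-Meier, log-rank, Cox, extended Cox.

Estimation is delegated to lifelines (Efron tie handling throughout); this
module owns the data contracts — in particular the conversion of a baseline
table plus a long-format biomarker table into counting-process rows
(start, stop] for the extended Cox model with step-function time-varying
covariates.

Intervals are half-open on the left: a row is at risk for an event at time
t iff start < t <= stop.  Consecutive intervals carrying identical
covariate values are merged, which makes the omit and LOCF versions of the
same cohort produce literally identical row sets (carrying the last
observation forward cannot change a step function built from last
observations), hence identical extended Cox fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "KaplanMeierEstimate",
    "kaplan_meier",
    "logrank_test",
    "fit_cox",
    "to_counting_process",
    "fit_extended_cox",
]


@dataclass
class KaplanMeierEstimate:
    """Right-continuous product-limit estimate of S(t)."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out


@dataclass
class CoxFit:
    gamma: pd.Series
    se: pd.Series
    wald_p: pd.Series
    loglik: float
    converged: bool
    n_patients: int
    n_events: int

    def significant(self, level: float = 0.05) -> pd.Series:
        return self.wald_p < level


def kaplan_meier(records: pd.DataFrame) -> KaplanMeierEstimate:
    """Kaplan-Meier estimate from a table with time_obs and status columns."""
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_obs"], event_observed=records["status"])
    sf = kmf.survival_function_
    return KaplanMeierEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


def logrank_test(records: pd.DataFrame, group_col: str) -> tuple[float, float]:
    """Log-rank chi-square test across the levels of ``group_col``."""
    groups = records[group_col]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs at least two groups")
    if records["status"].sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(
        records["time_obs"], groups, records["status"]
    )
    return float(res.test_statistic), float(res.p_value)


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson)."""
    df = records[["time_obs", "status", *covariates]].copy()
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="time_obs",
        event_col="status",
        show_progress=False,
        fit_options={"precision": tol, "max_steps": max_iter},
    )
    return CoxFit(
        gamma=cph.params_.rename(None),
        se=cph.standard_errors_.rename(None),
        wald_p=cph.summary["p"].rename(None),
        loglik=float(cph.log_likelihood_),
        converged=True,
        n_patients=len(df),
        n_events=int(df["status"].sum()),
    )


def to_counting_process(
    baseline: pd.DataFrame,
    longitudinal: pd.DataFrame,
    value_col: str = "y",
    out_col: str = "biomarker",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Expand to (start, stop] rows with a step-function biomarker covariate.

    The biomarker on each interval is the last measurement at or before the
    interval start.  Patients whose first measurement falls after 0 enter
    the risk set at that first measurement (delayed entry); patients with no
    measurement before their observed time are dropped with a log message.
    Consecutive rows with identical covariate values are merged.
    """
    covariates = covariates or []
    base = baseline.set_index("id")
    rows = []
    meas = {
        pid: sub.sort_values("t")[["t", value_col]].to_numpy()
        for pid, sub in longitudinal.groupby("id")
    }
    for pid, brow in base.iterrows():
        t_obs, status = float(brow["time_obs"]), int(brow["status"])
        m = meas.get(pid)
        if m is None or m[m[:, 0] < t_obs].size == 0:
            logger.info("patient %s has no usable measurement; dropped", pid)
            continue
        m = m[m[:, 0] < t_obs]
        t_meas, v_meas = m[:, 0], m[:, 1]
        # merge consecutive equal values so omit and LOCF coincide exactly
        keep = np.concatenate([[True], np.diff(v_meas) != 0.0])
        t_meas, v_meas = t_meas[keep], v_meas[keep]
        edges = np.append(t_meas, t_obs)
        for k in range(t_meas.size):
            start, stop = edges[k], edges[k + 1]
            if start >= t_obs:
                break
            ev = int(status == 1 and k == t_meas.size - 1)
            row = {
                "id": pid,
                "start": start,
                "stop": stop,
                "status": ev,
                out_col: v_meas[k],
            }
            for cname in covariates:
                row[cname] = brow[cname]
            rows.append(row)
    return pd.DataFrame(rows)


def fit_extended_cox(
    cp_rows: pd.DataFrame,
    covariates: list[str],
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Extended Cox fit on counting-process rows (risk iff start < t <= stop)."""
    df = cp_rows[["id", "start", "stop", "status", *covariates]].copy()
    ctv = CoxTimeVaryingFitter()
    ctv.fit(
        df,
        id_col="id",
        start_col="start",
        stop_col="stop",
        event_col="status",
        show_progress=False,
        fit_options={"precision": tol, "max_steps": max_iter},
    )
    return CoxFit(
        gamma=ctv.params_.rename(None),
        se=ctv.standard_errors_.rename(None),
        wald_p=ctv.summary["p"].rename(None),
        loglik=float(ctv.log_likelihood_),
        converged=True,
        n_patients=int(df["id"].nunique()),
        n_events=int(df["status"].sum()),
    )
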