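"""Eigen-survival modeling of a signature's realization.

A signature's realization in a cohort is the s x n sub-matrix of the
(preprocessed, row-centered) data holding the signature's variables.
Its dominant left singular vector — the eigen-survival model (ESM) —
gives each variable a loading; a patient's prognostic score is the inner
product of the loadings with that patient's profile.  Because the ESM
captures the dominant coordinated pattern across the signature, scores
are far less noisy than any single variable.  Patients with scores in
the top and bottom quartiles are compared by Kaplan–Meier/log-rank and
Cox proportional-hazards models; the signature is called predictive of
survival only when BOTH tests reach p <= 0.05.  The ESM fitted on a
discovery cohort projects unchanged onto an independent cohort's
realization of the same variables.

Censoring follows the 0 = event observed, 1 = censored convention
throughout; the ESM loading sign is fixed mathematically (largest
|loading| positive), so whether a high score is good or bad prognosis is
read off the hazard-ratio sign, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "EigenSurvivalModel",
    "KmSummary",
    "extract_esm",
    "project_scores",
    "quartile_groups",
    "logrank_test",
    "cox_ph",
    "km_summary",
    "predictive_of_survival",
]


@dataclass
class EigenSurvivalModel:
    """First left singular vector of a signature realization, plus train scores."""

    variable_ids: list[str]
    loadings: np.ndarray
    train_scores: np.ndarray


def extract_esm(signature_matrix: np.ndarray, variable_ids) -> EigenSurvivalModel:
    """Fit the ESM: unit-norm leading left singular vector of the s x n realization.

    The input should be the row-centered realization of the signature;
    the loading sign is fixed so the largest-magnitude loading is
    positive, and training scores are ``loadings^T @ matrix``.
    """
    A = np.asarray(signature_matrix, dtype=float)
    ids = [str(v) for v in variable_ids]
    if A.ndim != 2:
        raise ValueError("signature matrix must be 2-D")
    s, n = A.shape
    if s < 2 or n < 4:
        raise ValueError(f"need s >= 2 and n >= 4, got {(s, n)}")
    if len(ids) != s:
        raise ValueError("variable_ids length must equal the row count")
    if not np.any(A):
        raise ValueError("zero matrix has no eigen-survival model")
    U = np.linalg.svd(A, full_matrices=False)[0]
    w = U[:, 0]
    w = w * np.sign(w[np.argmax(np.abs(w))])
    return EigenSurvivalModel(variable_ids=ids, loadings=w, train_scores=w @ A)


def project_scores(
    esm: EigenSurvivalModel, new_matrix: np.ndarray, new_variable_ids
) -> np.ndarray:
    """Prognostic scores for a new cohort's realization of the same signature.

    Rows are matched to the ESM by variable ID (order-corrected); any
    missing variable is an error.
    """
    A = np.asarray(new_matrix, dtype=float)
    ids = [str(v) for v in new_variable_ids]
    if A.shape[0] != len(ids):
        raise ValueError("new_variable_ids length must equal the row count")
    pos = {v: i for i, v in enumerate(ids)}
    missing = [v for v in esm.variable_ids if v not in pos]
    if missing:
        raise ValueError(f"variables missing from new matrix: {missing}")
    idx = [pos[v] for v in esm.variable_ids]
    return esm.loadings @ A[idx]


def quartile_groups(scores: np.ndarray) -> np.ndarray:
    """Label the floor(m/4) largest scores "top", smallest "bottom", rest "middle".

    Boundary ties resolve by stable sample order. Score shifts and
    positive rescalings leave the grouping unchanged.
    """
    scores = np.asarray(scores, dtype=float)
    m = scores.shape[0]
    if m < 8:
        raise ValueError("need at least 8 samples for quartile groups")
    q = m // 4
    order = np.argsort(scores, kind="stable")
    labels = np.full(m, "middle", dtype=object)
    labels[order[:q]] = "bottom"
    labels[order[-q:]] = "top"
    return labels


def logrank_test(times, censored, group_labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    ``censored`` uses 1 = censored; the event indicator is its complement.
    """
    times = np.asarray(times, dtype=float)
    censored = np.asarray(censored, dtype=int)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {list(groups)}")
    events = 1 - censored
    if events.sum() < 1:
        raise ValueError("need at least one observed event")
    a, b = (labels == groups[0]), (labels == groups[1])
    res = _ll_logrank(
        times[a], times[b], event_observed_A=events[a], event_observed_B=events[b]
    )
    return float(res.test_statistic), float(res.p_value)


def cox_ph(times, censored, covariates: pd.DataFrame):
    """Cox proportional-hazards fit (Efron tie handling, Wald p-values).

    Returns (coefficients, standard errors, p-values) as Series indexed
    by covariate name.
    """
    times = np.asarray(times, dtype=float)
    censored = np.asarray(censored, dtype=int)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    events = 1 - censored
    if len(np.unique(times[events == 1])) < 2:
        raise ValueError("need at least two distinct event times")
    for col in cov.columns:
        x = cov[col].to_numpy(float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate {col!r} has non-finite values")
        if np.var(x) == 0:
            raise ValueError(f"covariate {col!r} is constant")
    df = cov.copy()
    df["time"] = times
    df["event"] = events
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return cph.params_, cph.standard_errors_, cph.summary["p"]


@dataclass
class KmSummary:
    """Kaplan–Meier product-limit curve with its headline statistics."""

    times: np.ndarray  # observed (event or censoring) times, ascending
    survival: np.ndarray  # S(t) at those times
    median: float  # smallest t with S(t) <= 0.5; nan if never reached
    horizon: float
    rate_at_horizon: float  # S at the last event time <= horizon


def km_summary(times, censored, horizon: float = 5.0) -> KmSummary:
    """Product-limit estimate plus median survival and the survival rate at
    ``horizon`` (e.g. 5 years, in whatever unit ``times`` uses)."""
    times = np.asarray(times, dtype=float)
    censored = np.asarray(censored, dtype=int)
    if times.size < 1:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=1 - censored)
    sf = kmf.survival_function_
    med = float(kmf.median_survival_time_)
    grid = np.sort(np.unique(times))
    return KmSummary(
        times=grid,
        survival=np.asarray(kmf.predict(grid), dtype=float).ravel(),
        median=np.nan if np.isinf(med) else med,
        horizon=float(horizon),
        rate_at_horizon=float(kmf.predict(horizon)),
    )


def predictive_of_survival(logrank_p: float, cox_p: float, alpha: float = 0.05) -> bool:
    """The predictive call: both the log-rank and Cox p-values must be <= alpha."""
    return logrank_p <= alpha and cox_p <= alpha
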