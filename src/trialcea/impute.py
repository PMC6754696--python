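"""Multiple imputation by bootstrap-EM under a multivariate normal model.

The trial handled missing outcome data (three telemonitoring-arm dropouts)
with five multivariate-normal imputations pooled by Rubin's rules.  This
module implements that algorithm family natively:

1. draw a nonparametric bootstrap resample of the records;
2. run EM to the multivariate-normal maximum-likelihood mean and covariance
   on the resample (missingness handled by conditional expectations);
3. fill each originally missing cell with a draw from the conditional normal
   of the missing block given the observed block under the bootstrap
   parameters.

Bootstrapping the EM parameters (rather than drawing them from an asymptotic
posterior) propagates estimation uncertainty between imputations.  Costs,
counts and hours enter on a log1p scale; utilities and percentages are
imputed on their natural scale and clipped to their support; counts are
rounded back to non-negative integers.  Treatment arm and baseline covariates
are columns of the model, so imputation respects the group structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import (Arm, Disease, PatientRecord, RESOURCE_COUNT_FIELDS,
                   TrialDataError)

METHOD_TAG = "bootstrap-em-mvn/log1p-counts/ridge0.05"


# ---------------------------------------------------------------------------
# EM for the multivariate normal with missing data


def em_mvn(X: np.ndarray, max_iter: int = 200, tol: float = 1e-6,
           ridge: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """ML mean and covariance of an MVN from data with missing entries.

    ``X`` is (n, p) with ``nan`` marking missing cells.  A small ridge
    (fraction of the mean diagonal) keeps the covariance invertible for
    near-collinear or low-variance columns.  Returns ``(mu, sigma)``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        bad = int(np.flatnonzero(miss.all(axis=0))[0])
        raise TrialDataError(f"EM: column {bad} has no observed values")
    mu = np.nanmean(X, axis=0)
    sigma = np.diag(np.nanvar(X, axis=0) + 1e-6)

    # group rows by missingness pattern for vectorised E-steps
    pattern_ids, pattern_index = np.unique(miss, axis=0, return_inverse=True)
    groups = [np.flatnonzero(pattern_index == k) for k in range(len(pattern_ids))]

    for _ in range(max_iter):
        ex = np.where(miss, 0.0, X)
        exx = np.zeros((p, p))
        for pat, rows in zip(pattern_ids, groups):
            o = ~pat
            m = pat
            xo = X[np.ix_(rows, o)]
            if not m.any():
                exx += _scatter(xo, o, p)
                continue
            soo = sigma[np.ix_(o, o)]
            som = sigma[np.ix_(o, m)]
            smm = sigma[np.ix_(m, m)]
            beta = np.linalg.solve(soo, som)           # (|o|, |m|)
            cond_mu = mu[m] + (xo - mu[o]) @ beta      # (r, |m|)
            cond_cov = smm - som.T @ beta              # (|m|, |m|)
            ex[np.ix_(rows, m)] = cond_mu
            # accumulate E[x x^T] for this pattern
            xr = ex[rows]
            s = xr.T @ xr
            idx = np.ix_(np.flatnonzero(m), np.flatnonzero(m))
            s[idx] += len(rows) * cond_cov
            exx += s
        mu_new = ex.mean(axis=0)
        sigma_new = exx / n - np.outer(mu_new, mu_new)
        sigma_new += ridge * np.mean(np.diag(sigma_new)) * np.eye(p) / n
        shift = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if shift < tol:
            break
    return mu, sigma


def _scatter(xo: np.ndarray, o: np.ndarray, p: int) -> np.ndarray:
    s = np.zeros((p, p))
    s[np.ix_(o, o)] = xo.T @ xo
    return s


def conditional_draw(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Fill the nan entries of one row with a conditional-normal draw."""
    m = np.isnan(x)
    if not m.any():
        return x.copy()
    o = ~m
    out = x.copy()
    if not o.any():
        cond_mu, cond_cov = mu[m], sigma[np.ix_(m, m)]
    else:
        soo = sigma[np.ix_(o, o)]
        som = sigma[np.ix_(o, m)]
        beta = np.linalg.solve(soo, som)
        cond_mu = mu[m] + (x[o] - mu[o]) @ beta
        cond_cov = sigma[np.ix_(m, m)] - som.T @ beta
    cond_cov = (cond_cov + cond_cov.T) / 2.0
    w, v = np.linalg.eigh(cond_cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    out[m] = cond_mu + root @ rng.standard_normal(m.sum())
    return out


def emb_impute_matrix(X: np.ndarray, m: int, rng: np.random.Generator,
                      max_iter: int = 200, tol: float = 1e-6,
                      ridge: float = 0.05) -> list[np.ndarray]:
    """m completed copies of ``X`` via bootstrap-EM; observed cells untouched."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    miss = np.isnan(X)
    if m < 2:
        raise TrialDataError(f"need m >= 2 imputations, got {m}")
    if not miss.any():
        return [X.copy() for _ in range(m)]
    if miss.all(axis=0).any():
        bad = int(np.flatnonzero(miss.all(axis=0))[0])
        raise TrialDataError(f"column {bad} is missing for all rows; cannot impute")
    completed = []
    for _ in range(m):
        for _attempt in range(20):
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if not np.isnan(Xb).all(axis=0).any():
                break
        else:
            raise TrialDataError("bootstrap resamples keep losing a whole column")
        mu, sigma = em_mvn(Xb, max_iter=max_iter, tol=tol, ridge=ridge)
        Xc = np.array([conditional_draw(row, mu, sigma, rng) for row in X])
        completed.append(Xc)
    return completed


# ---------------------------------------------------------------------------
# Record-level imputation


@dataclass
class ImputationSet:
    """m completed copies of a patient-record collection."""

    m: int
    datasets: list[list[PatientRecord]]
    seed: int
    method_tag: str = METHOD_TAG

    def __post_init__(self):
        if self.m < 2:
            raise TrialDataError(f"ImputationSet needs m >= 2, got {self.m}")
        if len(self.datasets) != self.m:
            raise TrialDataError("ImputationSet: len(datasets) != m")


class _Col:
    """One column of the imputation model: how to read/write a record field."""

    def __init__(self, name: str, get: Callable, set_: Callable | None,
                 kind: str, applies: Callable = lambda r: True):
        self.name, self.get, self.set, self.kind, self.applies = name, get, set_, kind, applies


def _wpai_get(week, attr):
    return lambda r: getattr(r.wpai[week], attr)


def _wpai_set(week, attr):
    def set_(r, v):
        setattr(r.wpai[week], attr, v)
    return set_


def _score_get(attr, week):
    return lambda r: getattr(r, attr)[week]


def _score_set(attr, week):
    def set_(r, v):
        getattr(r, attr)[week] = v
    return set_


def _columns() -> list[_Col]:
    cols: list[_Col] = []
    # fully observed covariates that inform the conditionals
    cols.append(_Col("arm_nt", lambda r: float(r.arm == Arm.NT), None, "cov"))
    cols.append(_Col("arm_teccu", lambda r: float(r.arm == Arm.TECCU), None, "cov"))
    cols.append(_Col("is_cd", lambda r: float(r.disease == Disease.CD), None, "cov"))
    cols.append(_Col("age", lambda r: r.age_years / 10.0, None, "cov"))
    cols.append(_Col("employed", lambda r: float(r.employed), None, "cov"))
    # clinical scores (disease-specific applicability)
    for attr, applies in (("hbi", lambda r: r.disease == Disease.CD),
                          ("sccai", lambda r: r.disease == Disease.UC),
                          ("pmayo", lambda r: r.disease == Disease.UC)):
        for wk in (0, 12, 24):
            cols.append(_Col(f"{attr}_w{wk}", _score_get(attr, wk), _score_set(attr, wk),
                             "score", applies))
    for wk in (0, 24):
        cols.append(_Col(f"eq5d_w{wk}", _score_get("eq5d", wk), _score_set("eq5d", wk),
                         "utility"))
    employed = lambda r: r.employed  # noqa: E731 - WPAI hours exist for workers only
    for wk in (0, 12, 24):
        cols.append(_Col(f"hours_missed_w{wk}", _wpai_get(wk, "hours_missed"),
                         _wpai_set(wk, "hours_missed"), "hours", employed))
        cols.append(_Col(f"hours_worked_w{wk}", _wpai_get(wk, "hours_worked"),
                         _wpai_set(wk, "hours_worked"), "hours", employed))
        cols.append(_Col(f"work_impairment_pct_w{wk}", _wpai_get(wk, "work_impairment_pct"),
                         _wpai_set(wk, "work_impairment_pct"), "pct", employed))
        cols.append(_Col(f"social_impairment_pct_w{wk}", _wpai_get(wk, "social_impairment_pct"),
                         _wpai_set(wk, "social_impairment_pct"), "pct"))

    def _res_get(f):
        return lambda r: getattr(r.resources, f)

    def _res_set(f):
        def set_(r, v):
            setattr(r.resources, f, v)
        return set_

    for f in RESOURCE_COUNT_FIELDS:
        applies = ((lambda r: r.arm == Arm.TECCU) if f.startswith("teccu")
                   else (lambda r: True))
        cols.append(_Col(f, _res_get(f), _res_set(f), "count", applies))
    return cols


def _forward(value: float, kind: str) -> float:
    if kind in ("count", "hours"):
        return math.log1p(value)
    return float(value)


def _backward(value: float, kind: str):
    if kind == "count":
        return int(round(max(math.expm1(value), 0.0)))
    if kind == "hours":
        return max(math.expm1(value), 0.0)
    if kind == "pct":
        return float(np.clip(value, 0.0, 100.0))
    if kind == "utility":
        return float(np.clip(value, -1.0, 1.0))
    if kind == "score":
        return max(float(value), 0.0)
    raise ValueError(kind)


def build_matrix(records: Sequence[PatientRecord]) -> tuple[np.ndarray, list[_Col], np.ndarray]:
    """Numeric design matrix for the imputation model.

    Returns (X with nan for missing, column spec, applicability mask).
    Structurally absent cells (e.g. HBI for UC patients, worker-only WPAI
    fields of non-workers) are nan but flagged not-applicable: they are never
    written back.
    """
    cols = _columns()
    n = len(records)
    X = np.full((n, len(cols)), np.nan)
    applicable = np.zeros((n, len(cols)), dtype=bool)
    for i, rec in enumerate(records):
        for j, col in enumerate(cols):
            app = col.applies(rec)
            applicable[i, j] = app and col.set is not None
            if not app:
                continue
            v = col.get(rec)
            if v is not None:
                X[i, j] = _forward(v, col.kind)
    return X, cols, applicable


def impute(records: Sequence[PatientRecord], m: int = 5, seed: int = 0,
           ridge: float = 0.05) -> ImputationSet:
    """m completed datasets via bootstrap-EM MVN imputation; fully seeded.

    Observed values are never altered; only cells that were missing (and are
    structurally applicable) are filled.  A variable that is missing for every
    applicable patient cannot be imputed and raises.
    """
    if m < 2:
        raise TrialDataError(f"need m >= 2 imputations, got {m}")
    records = list(records)
    X, cols, applicable = build_matrix(records)
    miss = np.isnan(X) & applicable
    for j, col in enumerate(cols):
        app_rows = applicable[:, j]
        if app_rows.any() and miss[app_rows, j].all() and np.isnan(X[app_rows, j]).all():
            raise TrialDataError(f"variable {col.name} is missing for all applicable "
                                 "patients; cannot impute")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if not miss.any():
        return ImputationSet(m=m, datasets=[[r.copy() for r in records] for _ in range(m)],
                             seed=seed)
    # drop columns with no observed values at all (purely structural)
    keep = ~np.isnan(X).all(axis=0)
    Xk = X[:, keep]
    completed = emb_impute_matrix(Xk, m=m, rng=rng, ridge=ridge)
    keep_idx = np.flatnonzero(keep)
    datasets = []
    for Xc in completed:
        ds = [r.copy() for r in records]
        for jk, j in enumerate(keep_idx):
            col = cols[j]
            if col.set is None:
                continue
            for i in np.flatnonzero(miss[:, j]):
                col.set(ds[i], _backward(Xc[i, jk], col.kind))
        for r in ds:
            r.validate()
        datasets.append(ds)
    return ImputationSet(m=m, datasets=datasets, seed=seed)


# ---------------------------------------------------------------------------
# Rubin's rules


def rubin_pool(estimates: Sequence[float],
               variances: Sequence[float] | None = None) -> tuple[float, float]:
    """Pool m completed-data point estimates by Rubin's rules.

    Returns ``(pooled_estimate, total_variance)`` with total variance
    W + (1 + 1/m) B, where W is the mean within-imputation variance and B the
    between-imputation variance of the estimates.
    """
    est = np.asarray(estimates, dtype=float)
    m = est.size
    if m < 2:
        raise TrialDataError(f"Rubin pooling needs m >= 2 estimates, got {m}")
    if variances is None:
        within = np.zeros(m)
    else:
        within = np.asarray(variances, dtype=float)
        if within.size != m:
            raise TrialDataError("rubin_pool: estimates and variances differ in length")
    pooled = est.mean()
    between = est.var(ddof=1)
    total = within.mean() + (1.0 + 1.0 / m) * between
    return float(pooled), float(total)
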