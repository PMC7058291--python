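"""Mass-univariate regression machinery shared by the GWAS and MWAS stages.

Implements a small iteratively-reweighted-least-squares logistic fitter
tuned for the one-feature-at-a-time design (thousands of fits per run,
each with a handful of columns), a fully vectorised OLS for the linear
MWAS, and Benjamini-Yekutieli FDR adjustment that keeps the total test
count fixed when individual fits fail to converge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, t as t_dist

from .datatypes import ASSOCIATION_COLUMNS

__all__ = [
    "logistic_irls",
    "mass_univariate_logistic",
    "mass_univariate_linear",
    "benjamini_yekutieli",
]

_P_FLOOR = 1e-300  # keep p strictly positive when z is enormous

_ETA_CLIP = 30.0


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
):
    """Fit a logistic regression by Newton/IRLS.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary outcome in {0, 1}.
    tol : relative deviance-change convergence tolerance.
    max_iter : Newton iteration cap.

    Returns
    -------
    beta : (p,) coefficient estimates.
    cov : (p, p) inverse observed information (Wald covariance).
    converged : bool; False on iteration cap, singular information, or
        quasi-separation (runaway coefficients).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    beta = np.zeros(p)
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(ybar / (1 - ybar))  # intercept warm start

    dev_old = np.inf
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        WX = X * w[:, None]
        H = X.T @ WX
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, np.full((p, p), np.nan), False
        beta = beta + step
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = -2.0 * np.sum(y * np.log(np.clip(mu, 1e-12, None))
                                + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None)))
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev

    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    if converged and not (np.isfinite(cov).all() and (np.diag(cov) > 0).all()):
        converged = False
    return beta, cov, converged


def _wald_p(beta: float, se: float) -> float:
    p = 2.0 * norm.sf(abs(beta / se))
    return max(p, _P_FLOOR)


def mass_univariate_logistic(
    features: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    feature_ids=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Per-feature logistic fits: ``y ~ 1 + feature_j + covariates``.

    ``features`` is (n, m); NaN entries drop the corresponding subjects
    for that feature only (``n_used`` records the count).  Each feature is
    internally standardised for numerical stability and the coefficient /
    SE mapped back to the original per-unit scale.  Constant features and
    non-converged fits are flagged (``converged`` False, p NaN), never
    dropped from the output.

    Returns a DataFrame with the :data:`ASSOCIATION_COLUMNS` contract
    (``p_adj`` left NaN for the caller's multiplicity correction).
    """
    features = np.atleast_2d(np.asarray(features, float))
    if features.shape[0] != len(y):
        features = features.T
    n, m = features.shape
    y = np.asarray(y, float)
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if C.size:  # standardize covariates for IRLS conditioning (fit unchanged)
        C = (C - C.mean(axis=0)) / np.where(C.std(axis=0) > 0, C.std(axis=0), 1.0)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(m)]

    base = np.column_stack([np.ones(n), np.zeros(n), C])
    rows = []
    for j in range(m):
        x = features[:, j]
        keep = ~np.isnan(x)
        n_used = int(keep.sum())
        xk = x[keep]
        sd = xk.std() if n_used else 0.0
        if n_used < C.shape[1] + 3 or sd == 0.0:
            rows.append((feature_ids[j], np.nan, np.nan, np.nan, np.nan, n_used, False))
            continue
        mu = xk.mean()
        if keep.all():
            X = base
        else:
            X = base[keep]
        X = X.copy()
        X[:, 1] = (xk - mu) / sd
        beta, cov, ok = logistic_irls(X, y[keep], tol=tol, max_iter=max_iter)
        if ok and abs(beta[1]) > 25.0:  # separation on the feature itself
            ok = False
        if not ok:
            rows.append((feature_ids[j], np.nan, np.nan, np.nan, np.nan, n_used, False))
            continue
        b = beta[1] / sd
        se = np.sqrt(cov[1, 1]) / sd
        rows.append((feature_ids[j], b, se, _wald_p(beta[1], np.sqrt(cov[1, 1])), np.nan, n_used, True))

    return pd.DataFrame(rows, columns=list(ASSOCIATION_COLUMNS))


def mass_univariate_linear(
    responses: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
    feature_ids=None,
) -> pd.DataFrame:
    """Vectorised OLS of many responses on one predictor plus covariates.

    Fits ``response_j ~ 1 + x + covariates`` for every column of
    ``responses`` (n, m) in a single pass; two-sided t-test on the ``x``
    slope.  Rows with NaN in ``x`` or the covariates are dropped globally.
    """
    Y = np.asarray(responses, float)
    x = np.asarray(x, float)
    n = Y.shape[0]
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    keep = ~np.isnan(x)
    if C.size:
        keep &= ~np.isnan(C).any(axis=1)
    Y, x, C = Y[keep], x[keep], C[keep]
    n_used = int(keep.sum())
    m = Y.shape[1]
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(m)]

    X = np.column_stack([np.ones(n_used), x, C])
    p_par = X.shape[1]
    dof = n_used - p_par
    if dof <= 0 or np.linalg.matrix_rank(X) < p_par:
        return pd.DataFrame(
            [(fid, np.nan, np.nan, np.nan, np.nan, n_used, False) for fid in feature_ids],
            columns=list(ASSOCIATION_COLUMNS),
        )
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)                       # (p, m)
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / dof         # (m,)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    beta = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    pvals = np.where(se > 0, 2.0 * t_dist.sf(np.abs(tval), dof), np.nan)
    pvals = np.clip(pvals, _P_FLOOR, 1.0)
    ok = se > 0

    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "beta": beta,
            "se": se,
            "p": np.where(ok, pvals, np.nan),
            "p_adj": np.nan,
            "n_used": n_used,
            "converged": ok,
        }
    )


def benjamini_yekutieli(p: np.ndarray, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Yekutieli FDR adjustment, valid under arbitrary dependence.

    ``p_adj(i) = min_{j >= i} [ m * c(m) * p_(j) / j ]`` with
    ``c(m) = sum_{k=1..m} 1/k``, monotone-enforced and capped at 1.

    NaN entries (non-converged tests) stay NaN but still count toward the
    total test number ``m`` (pass ``m_total`` to override, e.g. when the
    caller knows the full family size).  Matches
    ``statsmodels.stats.multitest.multipletests(method="fdr_by")`` when
    all p-values are present.
    """
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    m = int(m_total) if m_total is not None else p.size
    if m < valid.sum():
        raise ValueError("m_total smaller than the number of valid p-values")
    k = valid.sum()
    if k == 0:
        return out
    order = np.argsort(p[valid], kind="stable")
    p_sorted = p[valid][order]
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    ranks = np.arange(1, k + 1)
    adj = m * c_m * p_sorted / ranks
    adj = np.minimum.accumulate(adj[::-1])[::-1]  # monotone enforcement
    adj = np.clip(adj, 0.0, 1.0)
    tmp = np.empty(k)
    tmp[order] = adj
    out[valid] = tmp
    return out
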