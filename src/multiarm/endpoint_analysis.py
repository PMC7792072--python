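"""Comparative analyses for the trial's endpoints.

Time-to-event comparisons use a proportional-hazards regression fitted by
Newton–Raphson on the partial likelihood with Breslow handling of ties, and
the log-rank test (the score test of the single-covariate model).  Binary
comparisons use the pooled two-sample proportion z-test and a logistic
regression fitted by iteratively reweighted least squares.  The regressions
accept arbitrary covariate columns so the pooled-over-stages analyses can
adjust for trial stage and the stratification factors.

These are written against flat arrays so the Monte-Carlo operating
characteristics loop can call them cheaply; the DataFrame entry points are
thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PHFit", "LogisticFit",
    "fit_ph", "logrank", "logrank_arrays",
    "fit_logistic", "two_prop_test",
]

_MAX_ITER = 50
_GTOL = 1e-9
_BETA_DIVERGENCE = 50.0  # |beta| beyond this signals monotone likelihood


@dataclass(frozen=True)
class PHFit:
    """A fitted proportional-hazards regression."""

    coefficients: np.ndarray  # log hazard ratios
    standard_errors: np.ndarray
    covariate_names: tuple[str, ...]
    score_statistic: float  # global score chi-square at beta = 0
    score_df: int
    wald_z: np.ndarray
    wald_p_two_sided: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    separated: bool = False

    def hazard_ratio(self, name: str | int = 0) -> float:
        ix = name if isinstance(name, int) else self.covariate_names.index(name)
        return float(np.exp(self.coefficients[ix]))


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic regression (log-odds-ratio scale)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariate_names: tuple[str, ...]
    wald_z: np.ndarray
    wald_p_two_sided: np.ndarray
    loglik: float
    n: int
    converged: bool
    iterations: int
    separated: bool = False


def _design_matrix(table: pd.DataFrame, covariates) -> tuple[np.ndarray, tuple[str, ...]]:
    """Expand covariates to columns; multi-level integer columns to indicators."""
    cols, names = [], []
    for c in covariates:
        v = table[c].to_numpy()
        if np.issubdtype(v.dtype, np.floating):
            # continuous covariate: enter as-is
            cols.append(v.astype(float))
            names.append(c)
            continue
        uniq = np.unique(v)
        if len(uniq) <= 2:
            ref = uniq.min() if len(uniq) else 0
            cols.append((v != ref).astype(float))
            names.append(c)
        else:
            for lev in uniq[1:]:  # first level is the reference
                cols.append((v == lev).astype(float))
                names.append(f"{c}={lev}")
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return X, tuple(names)


# ---------------------------------------------------------------------------
# proportional hazards


def _ph_quantities(beta, t_order, e_order, X_order, uniq_inv, n_uniq):
    """Log-partial-likelihood, gradient and information (Breslow ties).

    Inputs are sorted by ascending time; ``uniq_inv`` maps each row to its
    unique-time group.  Risk-set sums are suffix sums over rows.
    """
    n, p = X_order.shape
    eta = X_order @ beta
    eta -= eta.max()  # guard overflow; cancels in all ratios
    w = np.exp(eta)
    Xw = X_order * w[:, None]
    # suffix sums: risk set of a time = all rows with t >= that time
    S0_row = np.cumsum(w[::-1])[::-1]
    S1_row = np.cumsum(Xw[::-1], axis=0)[::-1]
    outer = np.einsum("ij,ik->ijk", X_order, Xw)
    S2_row = np.cumsum(outer[::-1], axis=0)[::-1]
    # first row index of each unique-time group (rows are time-sorted)
    first = np.searchsorted(uniq_inv, np.arange(n_uniq), side="left")
    d = np.bincount(uniq_inv, weights=e_order, minlength=n_uniq)
    has_event = d > 0
    S0 = S0_row[first[has_event]]
    S1 = S1_row[first[has_event]]
    S2 = S2_row[first[has_event]]
    dd = d[has_event]
    ev = e_order.astype(bool)
    loglik = float(eta[ev].sum() - (dd * np.log(S0)).sum())
    xbar = S1 / S0[:, None]
    grad = X_order[ev].sum(axis=0) - (dd[:, None] * xbar).sum(axis=0)
    info = (dd[:, None, None] * (S2 / S0[:, None, None]
                                 - np.einsum("ij,ik->ijk", xbar, xbar))).sum(axis=0)
    return loglik, grad, info


def fit_ph(table: pd.DataFrame, covariates=("arm",), time_col: str = "time",
           event_col: str = "event") -> PHFit:
    """Proportional-hazards regression by Newton–Raphson, Breslow ties.

    ``covariates`` are column names; integer columns with more than two
    levels are expanded to indicator contrasts against the first level.
    Raises on datasets with no events; flags (rather than hides)
    non-convergence and monotone-likelihood separation.
    """
    t = table[time_col].to_numpy(dtype=float)
    e = table[event_col].to_numpy(dtype=float)
    n_events = int(e.sum())
    if n_events < 1:
        raise ValueError("proportional-hazards fit requires at least one event")
    X, names = _design_matrix(table, covariates)
    n, p = X.shape
    if p == 0:
        raise ValueError("no covariates to fit")
    order = np.argsort(t, kind="stable")
    t_o, e_o, X_o = t[order], e[order], X[order]
    uniq, uniq_inv = np.unique(t_o, return_inverse=True)
    n_uniq = len(uniq)

    beta = np.zeros(p)
    ll0, grad0, info0 = _ph_quantities(beta, t_o, e_o, X_o, uniq_inv, n_uniq)
    score_stat = float(grad0 @ np.linalg.solve(info0, grad0))
    ll = ll0
    converged = False
    separated = False
    it = 0
    grad, info = grad0, info0
    for it in range(1, _MAX_ITER + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halve until the likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            ll_new, grad_new, info_new = _ph_quantities(
                beta + factor * step, t_o, e_o, X_o, uniq_inv, n_uniq)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        ll, grad, info = ll_new, grad_new, info_new
        if np.abs(beta).max() > _BETA_DIVERGENCE:
            separated = True
            break
        if np.abs(grad).max() < _GTOL:
            converged = True
            break
    if np.abs(beta).max() > 10.0:
        # a |log HR| this large only arises from a monotone likelihood
        separated = True
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return PHFit(coefficients=beta, standard_errors=se, covariate_names=names,
                 score_statistic=score_stat, score_df=p, wald_z=z,
                 wald_p_two_sided=pvals, loglik=ll, n=n, n_events=n_events,
                 converged=converged, iterations=it, separated=separated)


# ---------------------------------------------------------------------------
# log-rank


def logrank_arrays(time: np.ndarray, event: np.ndarray, group: np.ndarray):
    """Two-group log-rank test on flat arrays.

    Returns ``(z, chi_square, p_two_sided)`` where ``z`` is the signed
    observed-minus-expected statistic for ``group == 1`` over its variance
    (negative when group 1 has fewer events than expected, i.e. does better).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    if len(np.unique(group)) != 2:
        raise ValueError("log-rank needs exactly two non-empty groups")
    if not event.any():
        raise ValueError("log-rank needs at least one event")
    g1 = group == np.max(group)
    order = np.argsort(time, kind="stable")
    t_o, e_o, g_o = time[order], event[order], g1[order]
    uniq, inv = np.unique(t_o, return_inverse=True)
    m = len(uniq)
    d = np.bincount(inv, weights=e_o, minlength=m)
    d1 = np.bincount(inv, weights=e_o & g_o, minlength=m)
    c = np.bincount(inv, minlength=m).astype(float)
    c1 = np.bincount(inv, weights=g_o, minlength=m)
    n_at = np.cumsum(c[::-1])[::-1]
    n1_at = np.cumsum(c1[::-1])[::-1]
    ev = d > 0
    d, d1, n_at, n1_at = d[ev], d1[ev], n_at[ev], n1_at[ev]
    frac = n1_at / n_at
    o_minus_e = float((d1 - d * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1 - frac) * (n_at - d) / np.where(n_at > 1, n_at - 1, 1)
    var = float(var_terms[n_at > 1].sum())
    if var <= 0:
        raise ValueError("log-rank variance is zero (degenerate risk sets)")
    z = o_minus_e / math.sqrt(var)
    chi = z * z
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(chi), float(p)


def logrank(table: pd.DataFrame, time_col: str = "time", event_col: str = "event",
            group_col: str = "arm") -> tuple[float, float]:
    """Log-rank test on an analysis table: ``(chi_square, p_two_sided)``."""
    _, chi, p = logrank_arrays(table[time_col].to_numpy(),
                               table[event_col].to_numpy().astype(bool),
                               table[group_col].to_numpy())
    return chi, p


# ---------------------------------------------------------------------------
# binary endpoint


def two_prop_test(x0: int, n0: int, x1: int, n1: int) -> tuple[float, float]:
    """Pooled-variance two-sample proportion z-test: ``(z, p_two_sided)``.

    ``z`` is positive when group 1's proportion exceeds group 0's.
    """
    if min(n0, n1) < 1:
        raise ValueError("both groups must be non-empty")
    p0, p1 = x0 / n0, x1 / n1
    pbar = (x0 + x1) / (n0 + n1)
    var = pbar * (1 - pbar) * (1 / n0 + 1 / n1)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p0) / math.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def fit_logistic(table: pd.DataFrame, covariates=("arm",),
                 response_col: str = "mrd_negative") -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    An intercept is always included.  Separation (diverging coefficients or
    singular weighted information) is flagged, never silently returned.
    """
    y = table[response_col].to_numpy(dtype=float)
    Xc, names = _design_matrix(table, covariates)
    X = np.column_stack([np.ones(len(y)), Xc])
    names = ("intercept",) + names
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    separated = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.abs(beta).max() > _BETA_DIVERGENCE:
            separated = True
            break
        if np.abs(grad).max() < 1e-8:
            converged = True
            break
    if np.abs(beta).max() > 10.0:
        separated = True  # complete/quasi-separation drives |log OR| unbounded
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    w = mu * (1 - mu)
    info = (X * w[:, None]).T @ X
    try:
        se = np.sqrt(np.clip(np.diag(np.linalg.inv(info)), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(coefficients=beta, standard_errors=se, covariate_names=names,
                       wald_z=z, wald_p_two_sided=pvals, loglik=ll, n=n,
                       converged=converged, iterations=it, separated=separated)
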