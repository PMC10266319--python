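"""Internal fitting machinery: logistic IRLS (with Firth fallback), design
matrices, and maximum-likelihood sub-model fits used by the model estimators.

Positivity-constrained parameters (NB dispersion, beta precision, Gaussian sd)
are optimised on the log scale; the ordered cumulative-logit cutpoints are
optimised as (first cutpoint, log successive differences). Analytic gradients
are supplied throughout so bootstrap refits stay cheap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit

from .outcome import ConfigError, DataError

GRAD_TOL = 1e-8


class SeparationWarning(UserWarning):
    """A logistic sub-model showed (quasi-)complete separation; a Jeffreys-
    penalised (Firth) fit was used instead of the diverging MLE."""


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# design matrices


class Design:
    """Treatment-coded design matrix builder with an intercept.

    Records category levels at fit time so new data map to the same columns;
    the first level of each categorical term is the reference.
    """

    def __init__(self, terms: list[str], data: pd.DataFrame):
        self.terms = list(terms)
        self.levels: dict[str, list] = {}
        missing = [t for t in self.terms if t not in data.columns]
        if missing:
            raise DataError(f"model terms {missing} not in data columns")
        for t in self.terms:
            col = data[t]
            if isinstance(col.dtype, pd.CategoricalDtype):
                self.levels[t] = [lv for lv in col.cat.categories]
            elif col.dtype == object or col.dtype == bool:
                self.levels[t] = list(pd.unique(col))
        self.columns = ["Intercept"]
        for t in self.terms:
            if t in self.levels:
                self.columns += [f"{t}[{lv}]" for lv in self.levels[t][1:]]
            else:
                self.columns.append(t)

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        missing = [t for t in self.terms if t not in data.columns]
        if missing:
            raise DataError(f"new data missing model terms {missing}")
        cols = [np.ones(len(data))]
        for t in self.terms:
            if t in self.levels:
                vals = np.asarray(data[t])
                known = set(self.levels[t])
                unknown = {v for v in pd.unique(data[t])} - known
                if unknown:
                    raise DataError(f"unknown level(s) {sorted(map(str, unknown))} for term {t!r}")
                for lv in self.levels[t][1:]:
                    cols.append((vals == lv).astype(float))
            else:
                cols.append(np.asarray(data[t], dtype=float))
        return np.column_stack(cols)

    @property
    def n_params(self) -> int:
        return len(self.columns)


# ---------------------------------------------------------------------------
# logistic regression (Newton / IRLS) with Firth fallback


def _logistic_irls(X, y, offset_penalty=False, max_iter=100, tol=1e-10):
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        W = np.clip(w, 1e-12, None)
        XtWX = X.T @ (X * W[:, None])
        if offset_penalty:
            # Firth: score += 0.5 * h_i * (1 - 2 mu_i) on each observation
            try:
                XtWX_inv = np.linalg.inv(XtWX)
            except np.linalg.LinAlgError:
                XtWX_inv = np.linalg.pinv(XtWX)
            h = np.einsum("ij,jk,ik->i", X * W[:, None], XtWX_inv, X)
            score = X.T @ (y - mu + h * (0.5 - mu))
        else:
            score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def fit_logistic(X: np.ndarray, y: np.ndarray, max_abs_coef: float = 12.0):
    """Logistic MLE with automatic Jeffreys-penalised (Firth) fallback.

    Complete separation sends the MLE to infinity; it is detected by
    non-convergence or runaway coefficients, in which case a Firth fit is
    returned with a :class:`SeparationWarning`.

    Returns ``(beta, penalized, converged)``.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        # all zeros or all ones: total separation on the intercept
        warnings.warn("logistic response is constant; using penalised fit",
                      SeparationWarning, stacklevel=2)
        beta, conv = _logistic_irls(X, y, offset_penalty=True)
        return beta, True, conv
    beta, conv = _logistic_irls(X, y)
    if not conv or np.max(np.abs(beta)) > max_abs_coef:
        warnings.warn(
            "(quasi-)complete separation in logistic sub-model; "
            "falling back to a Jeffreys-penalised (Firth) fit",
            SeparationWarning, stacklevel=2,
        )
        beta, conv = _logistic_irls(X, y, offset_penalty=True)
        return beta, True, conv
    return beta, False, conv


# ---------------------------------------------------------------------------
# zero-truncated NB regression: params = (beta..., log phi)


def _ztnb_nll_grad(params, X, y):
    p = X.shape[1]
    beta, logphi = params[:p], params[p]
    phi = np.exp(logphi)
    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    log_ratio = np.log(phi) - np.log(mu + phi)
    log_p0 = phi * log_ratio
    one_m_p0 = -np.expm1(log_p0)
    from scipy.special import gammaln
    ll = (gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
          + phi * log_ratio + y * (np.log(mu) - np.log(mu + phi))
          - np.log(one_m_p0))
    p0 = np.exp(log_p0)
    dll_dmu = y / mu - (y + phi) / (mu + phi) - p0 * phi / (one_m_p0 * (mu + phi))
    grad_beta = X.T @ (dll_dmu * mu)
    dp0_dphi = p0 * (log_ratio + mu / (mu + phi))
    dll_dphi = (digamma(y + phi) - digamma(phi) + log_ratio + 1
                - (y + phi) / (mu + phi) + dp0_dphi / one_m_p0)
    grad = np.concatenate([grad_beta, [phi * dll_dphi.sum()]])
    return -ll.sum(), -grad


def fit_ztnb(X, y, start=None):
    """Zero-truncated NB regression MLE (log link, log-scale dispersion)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 1):
        raise DataError("zero-truncated NB needs y >= 1")
    p = X.shape[1]
    if start is None:
        m = y.mean()
        v = max(y.var(ddof=1), m + 1e-6)
        phi0 = m**2 / max(v - m, 1e-3)
        start = np.zeros(p + 1)
        start[0] = np.log(m)
        start[p] = np.log(np.clip(phi0, 1e-2, 1e3))
    res = minimize(_ztnb_nll_grad, start, args=(X, y), jac=True,
                   method="L-BFGS-B", options={"gtol": GRAD_TOL, "ftol": 1e-13, "maxiter": 500})
    return res.x, bool(res.success)


# ---------------------------------------------------------------------------
# beta regression: params = (beta..., log phi_b)


def _betareg_nll_grad(params, X, y, logy, log1my):
    p = X.shape[1]
    beta, logphi = params[:p], params[p]
    phi = np.exp(logphi)
    mu = expit(X @ beta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    a, b = mu * phi, (1 - mu) * phi
    from scipy.special import betaln
    ll = (a - 1) * logy + (b - 1) * log1my - betaln(a, b)
    ystar = logy - log1my
    mustar = digamma(a) - digamma(b)
    dll_dmu = phi * (ystar - mustar)
    grad_beta = X.T @ (dll_dmu * mu * (1 - mu))
    dll_dphi = (mu * logy + (1 - mu) * log1my
                - mu * digamma(a) - (1 - mu) * digamma(b) + digamma(phi))
    grad = np.concatenate([grad_beta, [phi * dll_dphi.sum()]])
    return -ll.sum(), -grad


def fit_betareg(X, y, start=None):
    """Beta regression MLE (logit mean link, log-scale precision)."""
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise DataError("beta regression needs y strictly inside (0, 1)")
    p = X.shape[1]
    logy, log1my = np.log(y), np.log1p(-y)
    if start is None:
        m = y.mean()
        v = y.var(ddof=1)
        phi0 = m * (1 - m) / max(v, 1e-6) - 1
        start = np.zeros(p + 1)
        start[0] = np.log(m / (1 - m))
        start[p] = np.log(np.clip(phi0, 0.5, 1e4))
    res = minimize(_betareg_nll_grad, start, args=(X, y, logy, log1my), jac=True,
                   method="L-BFGS-B", options={"gtol": GRAD_TOL, "ftol": 1e-13, "maxiter": 500})
    return res.x, bool(res.success)


# ---------------------------------------------------------------------------
# cumulative logit: params = (zeta_1, log diff_2..K-1, beta...)
# theta_1 = zeta_1, theta_j = theta_{j-1} + exp(zeta_j)


def theta_from_zeta(zeta):
    theta = np.empty_like(zeta)
    theta[0] = zeta[0]
    if len(zeta) > 1:
        theta[1:] = zeta[0] + np.cumsum(np.exp(zeta[1:]))
    return theta


def zeta_from_theta(theta):
    theta = np.asarray(theta, dtype=float)
    zeta = np.empty_like(theta)
    zeta[0] = theta[0]
    if len(theta) > 1:
        zeta[1:] = np.log(np.diff(theta))
    return zeta


def _cumlogit_nll_grad(params, X, codes, K):
    ncut = K - 1
    zeta, beta = params[:ncut], params[ncut:]
    theta = theta_from_zeta(zeta)
    eta = X @ beta if len(beta) else np.zeros(X.shape[0])
    a_hi = np.where(codes < ncut, theta[np.minimum(codes, ncut - 1)] - eta, np.inf)
    a_lo = np.where(codes > 0, theta[np.maximum(codes - 1, 0)] - eta, -np.inf)
    P = expit(a_hi)
    Q = expit(a_lo)
    d = P - Q
    if np.any(d <= 0):
        return np.inf, np.zeros_like(params)
    ll = np.log(d)
    fP = np.where(np.isfinite(a_hi), P * (1 - P), 0.0)
    fQ = np.where(np.isfinite(a_lo), Q * (1 - Q), 0.0)
    # accumulate d ll / d theta_j
    g_theta = np.zeros(ncut)
    np.add.at(g_theta, np.clip(codes, None, ncut - 1), np.where(codes < ncut, fP / d, 0.0))
    np.add.at(g_theta, np.clip(codes - 1, 0, None), np.where(codes > 0, -fQ / d, 0.0))
    g_beta = -X.T @ ((fP - fQ) / d) if len(beta) else np.empty(0)
    # chain rule to zeta: dtheta_j/dzeta_1 = 1; dtheta_j/dzeta_i = exp(zeta_i) for i <= j
    g_zeta = np.empty(ncut)
    g_zeta[0] = g_theta.sum()
    if ncut > 1:
        rev_cum = np.cumsum(g_theta[::-1])[::-1]  # sum_{j >= i} g_theta[j]
        g_zeta[1:] = np.exp(zeta[1:]) * rev_cum[1:]
    grad = np.concatenate([g_zeta, g_beta])
    return -ll.sum(), -grad


def fit_cumlogit(X_noint, codes, K, start=None):
    """Proportional-odds MLE.

    ``X_noint`` excludes the intercept (absorbed by the cutpoints); ``codes``
    are 0-based category indices with K categories total.
    """
    codes = np.asarray(codes, dtype=int)
    n, p = X_noint.shape
    if start is None:
        freq = np.bincount(codes, minlength=K) + 0.5
        cum = np.cumsum(freq)[:-1] / freq.sum()
        theta0 = np.log(cum / (1 - cum))
        start = np.concatenate([zeta_from_theta(theta0), np.zeros(p)])
    res = minimize(_cumlogit_nll_grad, start, args=(X_noint, codes, K), jac=True,
                   method="L-BFGS-B", options={"gtol": GRAD_TOL, "ftol": 1e-13, "maxiter": 1000})
    zeta, beta = res.x[: K - 1], res.x[K - 1:]
    theta = theta_from_zeta(zeta)
    if len(theta) > 1:
        # a category empty in the data (possible in bootstrap replicates)
        # drives its cutpoint gap to 0; keep the ordering strict so every
        # draw satisfies the cutpoint invariant
        diffs = np.maximum(np.diff(theta), 1e-8)
        theta = np.concatenate([[theta[0]], theta[0] + np.cumsum(diffs)])
    return theta, beta, bool(res.success)
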