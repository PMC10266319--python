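"""Density and moment primitives for the four outcome regression families.

Parameterisations follow the conventions of Bayesian regression software:

* negative binomial in mean--dispersion form, ``Var = mu + mu^2/phi``, so the
  zero probability is ``p0 = (phi / (mu + phi))^phi``;
* beta in mean--precision form, ``Beta(mu_b * phi_b, (1 - mu_b) * phi_b)``;
* the zero--one-inflated beta (ZOIB) factorises as P(boundary) ->
  P(one | boundary) -> interior beta;
* the cumulative logit model has ``P(Y <= k) = F(theta_k - x beta)`` with F
  the logistic CDF, so a positive slope means higher (better) categories.

All functions broadcast over observation-length arrays so that a likelihood
can be evaluated on a parameter grid in one call.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, expit, gammaln, xlog1py, xlogy


def _check_positive(**kw):
    for name, v in kw.items():
        if np.any(np.asarray(v) <= 0):
            raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# negative binomial (mean-dispersion) and its zero-truncated form


def nb_logpmf(y, mu, phi):
    y = np.asarray(y, dtype=float)
    _check_positive(mu=mu, phi=phi)
    return (
        gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
        + phi * (np.log(phi) - np.log(mu + phi))
        + xlogy(y, mu) - xlogy(y, mu + phi)
    )


def nb_zero_prob(mu, phi):
    """P(Y = 0) for NB(mu, phi): ``(phi / (mu + phi))^phi``."""
    _check_positive(mu=mu, phi=phi)
    mu, phi = np.asarray(mu, float), np.asarray(phi, float)
    return np.exp(phi * (np.log(phi) - np.log(mu + phi)))


def truncated_nb_mean(mu, phi):
    """Conditional mean of the zero-truncated NB: ``mu / (1 - p0)``.

    Always exceeds ``mu`` and tends to 1 as ``mu -> 0`` (the truncated
    variable is at least 1).
    """
    _check_positive(mu=mu, phi=phi)
    mu = np.asarray(mu, dtype=float)
    return mu / -np.expm1(np.asarray(phi, float) * (np.log(phi) - np.log(mu + phi)))


def truncated_nb_logpmf(y, mu, phi):
    """log pmf of the zero-truncated NB for y >= 1."""
    y = np.asarray(y)
    if np.any(y < 1):
        raise ValueError("zero-truncated NB support is y >= 1")
    log_p0 = np.asarray(phi, float) * (np.log(phi) - np.log(np.asarray(mu, float) + phi))
    return nb_logpmf(y, mu, phi) - np.log(-np.expm1(log_p0))


def hurdle_nb_loglik(y, pi, mu, phi):
    """Hurdle-NB log likelihood.

    Zero observations contribute ``log pi``; positive observations contribute
    ``log(1 - pi)`` plus the zero-truncated NB log pmf.
    """
    y = np.asarray(y)
    pi = np.broadcast_to(np.asarray(pi, float), y.shape)
    mu = np.broadcast_to(np.asarray(mu, float), y.shape)
    if np.any(y < 0):
        raise ValueError("hurdle-NB support is y >= 0")
    ll = np.where(y == 0, np.log(pi), 0.0)
    pos = y > 0
    if pos.any():
        contrib = np.log1p(-pi[pos]) + truncated_nb_logpmf(y[pos], mu[pos], phi)
        ll = ll.astype(float)
        ll[pos] = contrib
    return float(ll.sum())


# ---------------------------------------------------------------------------
# beta (mean-precision) and zero-one-inflated beta


def beta_logpdf(y, mu_b, phi_b):
    """Beta log density with mean ``mu_b`` and precision ``phi_b``."""
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("beta support is the open interval (0, 1)")
    _check_positive(phi_b=phi_b)
    mu_b = np.asarray(mu_b, dtype=float)
    a = mu_b * phi_b
    b = (1.0 - mu_b) * phi_b
    return xlogy(a - 1.0, y) + xlog1py(b - 1.0, -y) - betaln(a, b)


def zoib_loglik(y, alpha, gamma, mu_b, phi_b):
    """Zero-one-inflated beta log likelihood on proportions in [0, 1].

    Boundary points: ``log alpha + log gamma`` (y == 1) or
    ``log alpha + log(1 - gamma)`` (y == 0); interior points:
    ``log(1 - alpha) + log Beta(y; mu_b, phi_b)``.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("ZOIB support is [0, 1]")
    alpha = np.broadcast_to(np.asarray(alpha, float), y.shape)
    gamma = np.broadcast_to(np.asarray(gamma, float), y.shape)
    mu_b = np.broadcast_to(np.asarray(mu_b, float), y.shape)
    ll = np.zeros_like(y)
    zero, one = (y == 0), (y == 1)
    interior = ~zero & ~one
    ll[zero] = np.log(alpha[zero]) + np.log1p(-gamma[zero])
    ll[one] = np.log(alpha[one]) + np.log(gamma[one])
    if interior.any():
        ll[interior] = (np.log1p(-alpha[interior])
                        + beta_logpdf(y[interior], mu_b[interior], phi_b))
    return float(ll.sum())


def zoib_mean_proportion(alpha, gamma, mu_b):
    """Expected proportion of the ZOIB mixture: ``alpha*gamma + (1-alpha)*mu_b``."""
    for name, v in (("alpha", alpha), ("gamma", gamma), ("mu_b", mu_b)):
        if np.any((np.asarray(v, float) < 0) | (np.asarray(v, float) > 1)):
            raise ValueError(f"{name} outside [0, 1]")
    alpha = np.asarray(alpha, dtype=float)
    return alpha * np.asarray(gamma, float) + (1.0 - alpha) * np.asarray(mu_b, float)


# ---------------------------------------------------------------------------
# cumulative logit


def cumlogit_category_probs(theta, eta):
    """Category probabilities of the proportional-odds model.

    ``p_k = F(theta_k - eta) - F(theta_{k-1} - eta)`` with logistic F and
    sentinels ``theta_0 = -inf``, ``theta_K = +inf``. ``eta`` may be a scalar
    or an observation vector; returns shape ``(n, K)`` (or ``(K,)`` for a
    scalar ``eta``).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or (len(theta) > 1 and np.any(np.diff(theta) <= 0)):
        raise ValueError("cutpoints theta must be strictly increasing")
    eta = np.asarray(eta, dtype=float)
    scalar = eta.ndim == 0
    eta = np.atleast_1d(eta)
    cdf = expit(theta[None, :] - eta[:, None])           # (n, K-1)
    full = np.concatenate(
        [np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))], axis=1
    )
    probs = np.diff(full, axis=1)
    return probs[0] if scalar else probs


def cumlogit_loglik(codes, theta, eta):
    """Log likelihood of observed category codes under the cumulative logit model."""
    probs = cumlogit_category_probs(theta, eta)
    probs = np.atleast_2d(probs)
    codes = np.asarray(codes, dtype=int)
    p = probs[np.arange(len(codes)), codes]
    if np.any(p <= 0):
        raise FloatingPointError("zero category probability at valid parameters")
    return float(np.log(p).sum())


def linear_loglik(y, mean, sigma):
    """Gaussian log likelihood."""
    _check_positive(sigma=sigma)
    y = np.asarray(y, dtype=float)
    r = y - np.asarray(mean, dtype=float)
    return float(-0.5 * np.sum(r**2) / sigma**2
                 - len(y) * (np.log(sigma) + 0.5 * np.log(2 * np.pi)))
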