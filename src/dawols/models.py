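"""Regression families for inflated count outcomes, as sklearn-style estimators.

Four families of increasing complexity, each fitted by maximum likelihood
with a parametric-bootstrap draws matrix standing in for posterior samples
(with flat priors the posterior mode coincides with the MLE, so bootstrap
draws carry the same downstream contract: every derived quantity is computed
per draw and summarised by median and 95% percentile interval):

* :class:`LinearModel` — Gaussian; models the mean with no range limits.
* :class:`HurdleNegBinomial` — logistic sub-model for P(y = 0) plus a
  zero-truncated negative binomial for the positive counts.
* :class:`ZeroOneInflatedBeta` — three sub-models on the proportion scale:
  P(boundary), P(one | boundary), and a beta density on the interior.
* :class:`CumulativeLogit` — proportional-odds ordinal regression over the
  observed outcome values, with death included as a category (-1) below all
  real day counts.

Estimators follow sklearn conventions: parameters in ``__init__``, data in
``fit(X, y)``, fitted attributes with trailing underscores, and
``get_params``/``set_params`` for composition with sklearn tooling. ``X`` is
a trial table (or covariate frame) containing an ``arm`` column; ``y``
defaults to its ``outcome`` column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from . import families
from ._optim import (
    ConvergenceWarning,
    Design,
    fit_betareg,
    fit_cumlogit,
    fit_logistic,
    fit_ztnb,
    zeta_from_theta,
)
from .outcome import ConfigError, DataError, to_ordinal_categories

FAMILIES = ("linear", "hurdle_nb", "zoib", "cumlogit")


@dataclass(frozen=True)
class SamplerConfig:
    """Contract for an optional pluggable posterior sampler.

    Mirrors the common MCMC setup for these models (4 chains, 10,000 total
    iterations of which 2,500 warmup, convergence gated on Rhat <= 1.01).
    A backend implementing this contract can replace the bootstrap engine;
    none is shipped.
    """

    chains: int = 4
    iterations: int = 10_000
    warmup: int = 2_500
    rhat_max: float = 1.01


def _as_frame(X, y):
    if not isinstance(X, pd.DataFrame):
        raise DataError("X must be a DataFrame with an 'arm' column")
    if y is None:
        if "outcome" not in X.columns:
            raise DataError("y not given and X has no 'outcome' column")
        y = X["outcome"]
    return X, np.asarray(y)


class BaseOutcomeModel(BaseEstimator):
    """Shared fitting/bootstrap machinery; subclasses define the family."""

    family: str = ""

    def __init__(self, terms=None, draws=1000, seed=None, engine="bootstrap",
                 sampler=None):
        self.terms = terms
        self.draws = draws
        self.seed = seed
        self.engine = engine
        self.sampler = sampler

    # ---- family hooks -----------------------------------------------------
    def _build(self, X: pd.DataFrame) -> None:
        raise NotImplementedError

    def _matrices(self, X: pd.DataFrame):
        raise NotImplementedError

    def _prepare_y(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float)

    def _fit_point(self, mats, y, start=None):
        raise NotImplementedError

    def _loglik(self, mats, y, params) -> float:
        raise NotImplementedError

    def _expected(self, mats, params) -> np.ndarray:
        raise NotImplementedError

    def _sample(self, mats, params, rng) -> np.ndarray:
        raise NotImplementedError

    # ---- common API -------------------------------------------------------
    def _default_terms(self, X):
        reserved = {"patient_id", "outcome", "died", "raw_count"}
        return ["arm"] + [c for c in X.columns if c not in reserved | {"arm"}]

    def fit(self, X, y=None):
        X, y = _as_frame(X, y)
        if "arm" not in X.columns:
            raise DataError("trial data must contain an 'arm' column")
        self.terms_ = list(self.terms) if self.terms is not None else self._default_terms(X)
        self._build(X)
        y_int = self._prepare_y(y)
        mats = self._matrices(X)
        self.n_obs_ = len(y_int)
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            self.point_, self.converged_ = self._fit_point(mats, y_int)
        self.loglik_ = self._loglik(mats, y_int, self.point_)
        if self.engine == "bootstrap":
            self.draws_, self.draw_converged_ = self._bootstrap(mats, y_int)
        elif self.engine == "sampler":
            if self.sampler is None:
                raise ConfigError("engine='sampler' requires a sampler callable")
            self.draws_ = np.asarray(self.sampler(self, mats, y_int))
            self.draw_converged_ = np.ones(len(self.draws_), dtype=bool)
        else:
            raise ConfigError(f"unknown engine {self.engine!r}")
        if not self.converged_:
            warnings.warn(f"{self.family} point fit did not converge",
                          ConvergenceWarning, stacklevel=2)
        self.n_draws_ = len(self.draws_)
        return self

    def _bootstrap(self, mats, y):
        D = int(self.draws)
        if D < 1:
            raise ConfigError("draws must be >= 1")
        rng = np.random.default_rng(self.seed)
        out = np.empty((D, len(self.point_)))
        flags = np.ones(D, dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation in individual replicates
            for d in range(D):
                y_star = self._sample(mats, self.point_, rng)
                y_star = self._prepare_y(y_star)
                try:
                    out[d], flags[d] = self._fit_point(mats, y_star, start=self.point_)
                except DataError:
                    # degenerate replicate (e.g. a sub-model lost all its
                    # observations); keep the point estimate, flag the draw
                    out[d], flags[d] = self.point_, False
        if not flags.all():
            warnings.warn(
                f"{int((~flags).sum())}/{D} bootstrap refits did not converge",
                ConvergenceWarning, stacklevel=3,
            )
        return out, flags

    def loglik(self, X, y=None, params=None):
        """Log likelihood of data under ``params`` (default: the MLE)."""
        X, y = _as_frame(X, y)
        mats = self._matrices(X)
        p = self.point_ if params is None else np.asarray(params, dtype=float)
        return self._loglik(mats, self._prepare_y(y), p)

    def predict(self, X):
        """Patient-level expected outcome (family-native scale) at the MLE."""
        mats = self._matrices(_as_frame(X, np.zeros(len(X)))[0])
        return self._expected(mats, self.point_)

    def expected_draws(self, X):
        """Expected outcome per draw and patient, shape ``(D, n)``."""
        mats = self._matrices(X)
        return np.vstack([self._expected(mats, p) for p in self.draws_])

    def sample_outcomes(self, X, params=None, rng=None):
        """Simulate one outcome per row of ``X`` from the generative model."""
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        mats = self._matrices(X)
        p = self.point_ if params is None else np.asarray(params, dtype=float)
        return self._sample(mats, p, rng)

    @property
    def params_(self) -> dict:
        return dict(zip(self.param_names_, self.point_))

    def summary(self) -> pd.DataFrame:
        """Point estimate plus draw median and 95% percentile interval."""
        lo, med, hi = np.percentile(self.draws_, [2.5, 50, 97.5], axis=0)
        return pd.DataFrame(
            {"estimate": self.point_, "median": med, "lower95": lo, "upper95": hi},
            index=self.param_names_,
        )


# ---------------------------------------------------------------------------


class LinearModel(BaseOutcomeModel):
    """Gaussian linear regression on the outcome value.

    Simple and interpretable; predictions are unconstrained, so predictive
    draws can fall below 0 or above the follow-up maximum.
    """

    family = "linear"

    def _build(self, X):
        self.design_ = Design(self.terms_, X)
        self.param_names_ = list(self.design_.columns) + ["sigma"]

    def _matrices(self, X):
        return {"X": self.design_.matrix(X)}

    def _fit_point(self, mats, y, start=None):
        Xm = mats["X"]
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid = y - Xm @ beta
        sigma = float(np.sqrt(np.mean(resid**2)))  # MLE scale
        return np.concatenate([beta, [max(sigma, 1e-12)]]), True

    def _split(self, params):
        return params[:-1], params[-1]

    def _loglik(self, mats, y, params):
        beta, sigma = self._split(params)
        return families.linear_loglik(y, mats["X"] @ beta, sigma)

    def _expected(self, mats, params):
        beta, _ = self._split(params)
        return mats["X"] @ beta

    def _sample(self, mats, params, rng):
        beta, sigma = self._split(params)
        return mats["X"] @ beta + rng.normal(0.0, sigma, size=mats["X"].shape[0])


class HurdleNegBinomial(BaseOutcomeModel):
    """Hurdle negative binomial: P(y = 0) by logistic regression, positive
    counts by a zero-truncated NB (log link, dispersion ``phi`` with
    ``Var = mu + mu^2/phi``).

    Suited to day counts with inflation at 0 (death penalisation plus
    patients never free of support); cannot produce values below 0, but has
    no built-in upper limit.
    """

    family = "hurdle_nb"

    def __init__(self, terms=None, draws=1000, seed=None, engine="bootstrap",
                 sampler=None, zero_terms=None, count_terms=None):
        super().__init__(terms=terms, draws=draws, seed=seed, engine=engine,
                         sampler=sampler)
        self.zero_terms = zero_terms
        self.count_terms = count_terms

    def _build(self, X):
        self.zero_design_ = Design(self.zero_terms or self.terms_, X)
        self.count_design_ = Design(self.count_terms or self.terms_, X)
        self.param_names_ = (
            [f"zero__{c}" for c in self.zero_design_.columns]
            + [f"count__{c}" for c in self.count_design_.columns]
            + ["phi"]
        )
        self._pz = self.zero_design_.n_params
        self._pc = self.count_design_.n_params

    def _matrices(self, X):
        return {"Xz": self.zero_design_.matrix(X), "Xc": self.count_design_.matrix(X)}

    def _prepare_y(self, y):
        y = np.asarray(y)
        if np.any(y < 0):
            raise DataError(
                "hurdle-NB support is y >= 0; use death_handling='penalize_zero' "
                "or 'actual', not the ordinal -1 code"
            )
        if not np.allclose(y, np.round(y)):
            raise DataError("hurdle-NB needs integer counts")
        return np.asarray(y, dtype=float)

    def _split(self, params):
        bz = params[: self._pz]
        bc = params[self._pz: self._pz + self._pc]
        return bz, bc, params[-1]

    def _fit_point(self, mats, y, start=None):
        zero = (y == 0).astype(float)
        if zero.sum() == len(y):
            raise DataError("hurdle-NB needs at least one positive count")
        bz, _, conv_z = fit_logistic(mats["Xz"], zero)
        pos = y > 0
        ztnb_start = None
        if start is not None:
            _, bc0, phi0 = self._split(start)
            ztnb_start = np.concatenate([bc0, [np.log(phi0)]])
        theta, conv_c = fit_ztnb(mats["Xc"][pos], y[pos], start=ztnb_start)
        bc, phi = theta[:-1], float(np.exp(theta[-1]))
        return np.concatenate([bz, bc, [phi]]), bool(conv_z and conv_c)

    def _loglik(self, mats, y, params):
        bz, bc, phi = self._split(params)
        pi = expit(mats["Xz"] @ bz)
        mu = np.exp(mats["Xc"] @ bc)
        return families.hurdle_nb_loglik(y, pi, mu, phi)

    def _expected(self, mats, params):
        bz, bc, phi = self._split(params)
        pi = expit(mats["Xz"] @ bz)
        mu = np.exp(mats["Xc"] @ bc)
        return (1.0 - pi) * families.truncated_nb_mean(mu, phi)

    def _sample(self, mats, params, rng):
        bz, bc, phi = self._split(params)
        n = mats["Xz"].shape[0]
        pi = expit(mats["Xz"] @ bz)
        mu = np.exp(mats["Xc"] @ bc)
        y = np.zeros(n)
        pos = rng.random(n) >= pi
        if pos.any():
            y[pos] = _sample_ztnb(mu[pos], phi, rng)
        return y


def _sample_ztnb(mu, phi, rng, max_rounds=200):
    """Vectorised rejection sampling from the zero-truncated NB."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=float)
    todo = np.ones(mu.shape, dtype=bool)
    p = phi / (phi + mu)
    for _ in range(max_rounds):
        if not todo.any():
            break
        draw = rng.negative_binomial(phi, p[todo])
        accept = draw >= 1
        idx = np.flatnonzero(todo)
        out[idx[accept]] = draw[accept]
        todo[idx[accept]] = False
    out[todo] = 1.0  # mu ~ 0: truncated NB collapses onto 1
    return out


class ZeroOneInflatedBeta(BaseOutcomeModel):
    """Zero-one-inflated beta regression on the proportion of days.

    Three sub-models (all logit-linked): the probability ``alpha`` of a
    boundary value (0 or 1), the probability ``gamma`` of 1 given a boundary
    value, and a beta density (mean ``mu_b``, precision ``phi_b``) on the
    interior. Predictions are confined to [0, 1] by construction. Boundary
    membership must be decided on the integer day counts upstream
    (:func:`dawols.outcome.to_proportion`), never by float comparison.
    """

    family = "zoib"

    def __init__(self, terms=None, draws=1000, seed=None, engine="bootstrap",
                 sampler=None, boundary_terms=None, one_terms=None, beta_terms=None):
        super().__init__(terms=terms, draws=draws, seed=seed, engine=engine,
                         sampler=sampler)
        self.boundary_terms = boundary_terms
        self.one_terms = one_terms
        self.beta_terms = beta_terms

    def _build(self, X):
        self.boundary_design_ = Design(self.boundary_terms or self.terms_, X)
        self.one_design_ = Design(self.one_terms or self.terms_, X)
        self.beta_design_ = Design(self.beta_terms or self.terms_, X)
        self.param_names_ = (
            [f"boundary__{c}" for c in self.boundary_design_.columns]
            + [f"one__{c}" for c in self.one_design_.columns]
            + [f"beta__{c}" for c in self.beta_design_.columns]
            + ["phi_b"]
        )
        self._pa = self.boundary_design_.n_params
        self._pg = self.one_design_.n_params
        self._pb = self.beta_design_.n_params

    def _matrices(self, X):
        return {
            "Xa": self.boundary_design_.matrix(X),
            "Xg": self.one_design_.matrix(X),
            "Xb": self.beta_design_.matrix(X),
        }

    def _prepare_y(self, y):
        y = np.asarray(y, dtype=float)
        if np.any((y < 0) | (y > 1)):
            raise DataError("ZOIB needs proportions in [0, 1]; rescale days first")
        return y

    def _split(self, params):
        ba = params[: self._pa]
        bg = params[self._pa: self._pa + self._pg]
        bb = params[self._pa + self._pg: self._pa + self._pg + self._pb]
        return ba, bg, bb, params[-1]

    def _fit_point(self, mats, y, start=None):
        boundary = (y == 0.0) | (y == 1.0)
        interior = ~boundary
        if not interior.any():
            raise DataError("ZOIB needs at least one interior (0 < y < 1) value")
        ba, _, ca = fit_logistic(mats["Xa"], boundary.astype(float))
        if boundary.any():
            bg, _, cg = fit_logistic(mats["Xg"][boundary],
                                     (y[boundary] == 1.0).astype(float))
        elif start is not None:
            _, bg, _, _ = self._split(start)
            cg = False
        else:
            raise DataError("ZOIB needs at least one boundary (0 or 1) value")
        beta_start = None
        if start is not None:
            _, _, bb0, phi0 = self._split(start)
            beta_start = np.concatenate([bb0, [np.log(phi0)]])
        theta, cb = fit_betareg(mats["Xb"][interior], y[interior], start=beta_start)
        bb, phi_b = theta[:-1], float(np.exp(theta[-1]))
        return np.concatenate([ba, bg, bb, [phi_b]]), bool(ca and cg and cb)

    def _loglik(self, mats, y, params):
        ba, bg, bb, phi_b = self._split(params)
        alpha = expit(mats["Xa"] @ ba)
        gamma = expit(mats["Xg"] @ bg)
        mu_b = expit(mats["Xb"] @ bb)
        return families.zoib_loglik(y, alpha, gamma, mu_b, phi_b)

    def _expected(self, mats, params):
        ba, bg, bb, _ = self._split(params)
        alpha = expit(mats["Xa"] @ ba)
        gamma = expit(mats["Xg"] @ bg)
        mu_b = expit(mats["Xb"] @ bb)
        return families.zoib_mean_proportion(alpha, gamma, mu_b)

    def _sample(self, mats, params, rng):
        ba, bg, bb, phi_b = self._split(params)
        n = mats["Xa"].shape[0]
        alpha = expit(mats["Xa"] @ ba)
        gamma = expit(mats["Xg"] @ bg)
        mu_b = expit(mats["Xb"] @ bb)
        y = np.empty(n)
        at_boundary = rng.random(n) < alpha
        y[at_boundary] = (rng.random(int(at_boundary.sum())) < gamma[at_boundary]).astype(float)
        interior = ~at_boundary
        if interior.any():
            a = mu_b[interior] * phi_b
            b = (1 - mu_b[interior]) * phi_b
            draw = rng.beta(a, b)
            # keep generative interior values off the exact boundary so the
            # boundary indicator stays identified on refits
            y[interior] = np.clip(draw, 1e-9, 1 - 1e-9)
        return y


class CumulativeLogit(BaseOutcomeModel):
    """Proportional-odds (cumulative logistic) regression on ordinal outcomes.

    Categories are the distinct observed values sorted ascending, with the
    death code -1 (when present) as the worst category. ``P(Y <= k) =
    F(theta_k - x beta)``; a positive arm coefficient means better (higher)
    categories, and ``exp(beta_arm)`` is the cumulative odds ratio. The
    single set of slopes across all cutpoints is the proportional-odds
    assumption.
    """

    family = "cumlogit"

    def _build(self, X):
        d = Design(self.terms_, X)
        self.design_ = d
        self._coef_names = d.columns[1:]  # intercept absorbed by cutpoints

    def _matrices(self, X):
        return {"X": self.design_.matrix(X)[:, 1:]}

    def fit(self, X, y=None):
        X, y = _as_frame(X, y)
        codes, self.value_map_ = to_ordinal_categories(y)
        self.n_categories_ = len(self.value_map_)
        self.param_names_ = (
            [f"cut[{v}|{w}]" for v, w in zip(self.value_map_[:-1], self.value_map_[1:])]
            + [f"beta__{c}" for c in self._coef_names_pending(X)]
        )
        return super().fit(X, y)

    def _coef_names_pending(self, X):
        self.terms_ = list(self.terms) if self.terms is not None else self._default_terms(X)
        self._build(X)
        return self._coef_names

    def _prepare_y(self, y):
        y = np.asarray(y)
        if y.dtype.kind == "f" and np.allclose(y, np.round(y)):
            y = np.round(y).astype(int)
        codes = np.searchsorted(self.value_map_, y)
        if (np.any(codes >= len(self.value_map_))
                or np.any(np.asarray(self.value_map_)[codes] != y)):
            raise DataError("outcome value outside the fitted category map")
        return codes

    def _split(self, params):
        ncut = self.n_categories_ - 1
        return params[:ncut], params[ncut:]

    def _fit_point(self, mats, codes, start=None):
        ncut = self.n_categories_ - 1
        s = None
        if start is not None:
            theta0, beta0 = self._split(start)
            s = np.concatenate([zeta_from_theta(theta0), beta0])
        theta, beta, conv = fit_cumlogit(mats["X"], codes, self.n_categories_, start=s)
        return np.concatenate([theta, beta]), conv

    def _loglik(self, mats, codes, params):
        theta, beta = self._split(params)
        eta = mats["X"] @ beta if mats["X"].shape[1] else np.zeros(len(codes))
        return families.cumlogit_loglik(codes, theta, eta)

    def category_probs(self, X, params=None):
        """Category probability matrix ``(n, K)`` at ``params`` (default MLE)."""
        mats = self._matrices(X)
        p = self.point_ if params is None else np.asarray(params, dtype=float)
        theta, beta = self._split(p)
        eta = mats["X"] @ beta if mats["X"].shape[1] else np.zeros(mats["X"].shape[0])
        return families.cumlogit_category_probs(theta, eta)

    def _expected(self, mats, params, values=None):
        theta, beta = self._split(params)
        eta = mats["X"] @ beta if mats["X"].shape[1] else np.zeros(mats["X"].shape[0])
        v = np.asarray(self.value_map_ if values is None else values, dtype=float)
        probs = families.cumlogit_category_probs(theta, eta)
        return probs @ v

    def expected_draws(self, X, values=None):
        mats = self._matrices(X)
        return np.vstack([self._expected(mats, p, values=values) for p in self.draws_])

    def _sample(self, mats, params, rng):
        theta, beta = self._split(params)
        eta = mats["X"] @ beta if mats["X"].shape[1] else np.zeros(mats["X"].shape[0])
        probs = families.cumlogit_category_probs(theta, eta)
        u = rng.random(len(eta))
        codes = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        return np.asarray(self.value_map_)[np.clip(codes, 0, self.n_categories_ - 1)]


MODEL_CLASSES = {
    "linear": LinearModel,
    "hurdle_nb": HurdleNegBinomial,
    "zoib": ZeroOneInflatedBeta,
    "cumlogit": CumulativeLogit,
}


def fit_model(family: str, data: pd.DataFrame, y=None, **engine_config) -> BaseOutcomeModel:
    """Fit one family to a trial table; thin wrapper over the estimators.

    ``engine_config`` maps to estimator parameters (``terms``, ``draws``,
    ``seed``, ``engine``, per-sub-model term lists).
    """
    if family not in MODEL_CLASSES:
        raise ConfigError(f"unknown family {family!r}; choose from {FAMILIES}")
    return MODEL_CLASSES[family](**engine_config).fit(data, y)


def sample_predictive(fit: BaseOutcomeModel, data: pd.DataFrame, n_rep: int,
                      seed=None, max_days: int | None = None):
    """Replicated outcome vectors from the fitted model's draws.

    Each replicate picks one parameter draw and simulates one outcome per
    patient from the family's generative form. Returns ``(raw, clamped)``
    arrays of shape ``(n_rep, n)``: ``raw`` on the family's native scale
    (days, proportion, or category value) and ``clamped`` on the days scale,
    truncated to the valid outcome space when ``max_days`` is given.
    """
    rng = np.random.default_rng(seed)
    mats = fit._matrices(data)
    n = len(data)
    raw = np.empty((n_rep, n))
    D = len(fit.draws_)
    idx = rng.integers(0, D, size=n_rep)
    for r in range(n_rep):
        raw[r] = fit._sample(mats, fit.draws_[idx[r]], rng)
    clamped = raw.copy()
    if fit.family == "zoib" and max_days is not None:
        clamped = clamped * max_days
    if max_days is not None:
        lo = -1.0 if (fit.family == "cumlogit" and min(fit.value_map_) == -1) else 0.0
        clamped = np.clip(clamped, lo, max_days)
    return raw, clamped
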