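import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from sklearn.base import clone

import dawols as dw
from dawols._optim import SeparationWarning, fit_cumlogit
from dawols.models import FAMILIES, _sample_ztnb
from dawols.outcome import DataError

from conftest import recode_for_family


def trial_frame(y, arm, died=None, **covs):
    df = pd.DataFrame({"patient_id": [f"p{i}" for i in range(len(y))],
                       "arm": pd.Categorical(arm, categories=sorted(set(arm)),
                                             ordered=True),
                       "outcome": y,
                       "died": died if died is not None else [False] * len(y)})
    for k, v in covs.items():
        df[k] = v
    return df


class TestExactInterceptOnlyFits:
    def test_linear_saturated_arm_means_equal_sample_means(self, covid_trial):
        fit = dw.LinearModel(draws=1, seed=0).fit(covid_trial)
        pred = fit.predict(covid_trial)
        for arm in ("control", "intervention"):
            sel = covid_trial["arm"] == arm
            assert pred[sel.to_numpy()][0] == pytest.approx(
                covid_trial.loc[sel, "outcome"].mean(), abs=1e-8)

    def test_hurdle_intercept_only_zero_prob_is_zero_fraction(self, covid_trial):
        fit = dw.HurdleNegBinomial(terms=[], draws=1, seed=0).fit(covid_trial)
        pi_hat = expit(fit.params_["zero__Intercept"])
        assert pi_hat == pytest.approx((covid_trial["outcome"] == 0).mean(), abs=1e-6)

    def test_cumlogit_intercept_only_probs_are_empirical_freqs(self, covid_trial):
        fit = dw.CumulativeLogit(terms=[], draws=1, seed=0).fit(covid_trial)
        probs = fit.category_probs(covid_trial.iloc[:1])[0]
        y = covid_trial["outcome"].to_numpy()
        freqs = np.array([(y == v).mean() for v in fit.value_map_])
        assert np.allclose(probs, freqs, atol=1e-6)

    def test_zoib_intercept_only_boundary_prob_is_boundary_fraction(
            self, covid_trial, spec_days):
        zdf = recode_for_family(covid_trial, spec_days, "zoib")
        fit = dw.ZeroOneInflatedBeta(terms=[], draws=1, seed=0).fit(zdf)
        y = zdf["outcome"].to_numpy()
        alpha_hat = expit(fit.params_["boundary__Intercept"])
        assert alpha_hat == pytest.approx(((y == 0) | (y == 1)).mean(), abs=1e-6)
        gamma_hat = expit(fit.params_["one__Intercept"])
        boundary = y[(y == 0) | (y == 1)]
        assert gamma_hat == pytest.approx((boundary == 1).mean(), abs=1e-6)


class TestLocalMaximum:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_loglik_at_mle_beats_random_perturbations(self, family, fitted):
        fits, datasets = fitted
        fit, data = fits[family], datasets[family]
        ll_hat = fit.loglik(data)
        rng = np.random.default_rng(17)
        beaten = 0
        for _ in range(100):
            p = fit.point_.copy()
            p = p + rng.normal(0, 0.05, size=p.shape)
            if family in ("hurdle_nb", "zoib"):
                p[-1] = abs(p[-1])  # keep dispersion positive
            if family == "cumlogit":
                ncut = fit.n_categories_ - 1
                p[:ncut] = np.sort(p[:ncut])
            try:
                beaten += fit.loglik(data, params=p) <= ll_hat + 1e-9
            except FloatingPointError:
                beaten += 1
        assert beaten == 100


class TestCumlogitReference:
    def test_binary_cumlogit_matches_statsmodels_logit(self):
        # K=2 proportional odds == logistic regression; statsmodels as oracle
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.5 + 1.2 * x)).astype(int)
        theta, beta, conv = fit_cumlogit(x[:, None], y, K=2)
        assert conv
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        # P(Y=1) = F(x beta - theta): intercept = -theta, slope = beta
        assert -theta[0] == pytest.approx(ref.params[0], abs=1e-6)
        assert beta[0] == pytest.approx(ref.params[1], abs=1e-6)

    def test_multicategory_cumlogit_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        tr = dw.simulate_proportional_odds(
            [0.25, 0.3, 0.25, 0.2], [0, 1, 2, 3], log_or=0.7,
            n_per_arm=400, seed=10)
        fit = dw.CumulativeLogit(draws=1, seed=0).fit(tr)
        x = (tr["arm"] == "intervention").astype(float).to_numpy()
        ref = OrderedModel(tr["outcome"].to_numpy(), x[:, None],
                           distr="logit").fit(method="bfgs", disp=0)
        # statsmodels: P(Y<=k) = F(cut_k - x beta), same orientation
        assert fit.params_["beta__arm[intervention]"] == pytest.approx(
            ref.params[0], abs=1e-4)
        cuts = np.concatenate([[ref.params[1]],
                               ref.params[1] + np.cumsum(np.exp(ref.params[2:]))])
        assert np.allclose(fit.point_[:3], cuts, atol=1e-4)


class TestParameterRecovery:
    def test_hurdle_recovers_known_parameters(self):
        # simulate from known hurdle-NB parameters, fit, check 3 bootstrap SEs
        rng = np.random.default_rng(123)
        n = 2000
        arm = np.repeat(["c", "i"], n)
        true = {"zero__Intercept": logit(0.35), "zero__arm[i]": -0.4,
                "count__Intercept": np.log(12.0), "count__arm[i]": 0.15, "phi": 2.5}
        xi = (arm == "i").astype(float)
        pi = expit(true["zero__Intercept"] + true["zero__arm[i]"] * xi)
        mu = np.exp(true["count__Intercept"] + true["count__arm[i]"] * xi)
        y = np.zeros(2 * n)
        pos = rng.random(2 * n) >= pi
        y[pos] = _sample_ztnb(mu[pos], true["phi"], rng)
        df = trial_frame(y.astype(int), arm)
        fit = dw.HurdleNegBinomial(draws=150, seed=99).fit(df)
        se = fit.draws_.std(axis=0)
        for j, name in enumerate(fit.param_names_):
            assert abs(fit.point_[j] - true[name]) < 3 * se[j], name

    def test_linear_bootstrap_se_matches_theory(self):
        rng = np.random.default_rng(5)
        y = rng.normal(10, 4, 800)
        df = trial_frame(y, ["c"] * 400 + ["i"] * 400)
        fit = dw.LinearModel(draws=400, seed=1).fit(df)
        se_int = fit.draws_[:, 0].std()
        assert se_int == pytest.approx(4 / np.sqrt(400), rel=0.25)


class TestSeparationFallback:
    def test_arm_without_zeros_triggers_penalised_fit(self):
        y = np.concatenate([np.zeros(30), np.ones(70) * 5,
                            np.ones(100) * 6]).astype(int)
        arm = ["c"] * 100 + ["i"] * 100  # intervention arm has no zeros
        df = trial_frame(y, arm)
        with pytest.warns(SeparationWarning):
            fit = dw.HurdleNegBinomial(draws=1, seed=0).fit(df)
        assert np.all(np.isfinite(fit.point_))
        assert abs(fit.params_["zero__arm[i]"]) < 20


class TestSamplePredictive:
    def test_degenerate_zero_part_gives_all_zero_replicates(self, covid_trial):
        fit = dw.HurdleNegBinomial(terms=[], draws=1, seed=0).fit(covid_trial)
        fit.point_ = fit.point_.copy()
        fit.point_[0] = 30.0  # pi ~ 1
        fit.draws_ = fit.point_[None, :]
        raw, clamped = dw.sample_predictive(fit, covid_trial, n_rep=5, seed=0,
                                            max_days=28)
        assert (raw == 0).all() and (clamped == 0).all()

    def test_replicate_means_bracket_fitted_mean(self, fitted, covid_trial, spec_days):
        fits, datasets = fitted
        fit, data = fits["hurdle_nb"], datasets["hurdle_nb"]
        _, clamped = dw.sample_predictive(fit, data, n_rep=400, seed=2, max_days=28)
        rep_means = clamped.mean(axis=1)
        fitted_mean = fit.predict(data).mean()
        lo, hi = np.percentile(rep_means, [1, 99])
        assert lo < fitted_mean < hi

    def test_linear_replicates_escape_valid_space(self, covid_trial):
        fit = dw.LinearModel(draws=5, seed=0).fit(covid_trial)
        raw, clamped = dw.sample_predictive(fit, covid_trial, n_rep=20, seed=1,
                                            max_days=28)
        assert ((raw < 0) | (raw > 28)).mean() > 0.01  # sigma ~ 11: plenty outside
        assert clamped.min() >= 0 and clamped.max() <= 28

    def test_reproducible_given_seed(self, fitted):
        fits, datasets = fitted
        fit, data = fits["linear"], datasets["linear"]
        a = dw.sample_predictive(fit, data, n_rep=3, seed=42)[0]
        b = dw.sample_predictive(fit, data, n_rep=3, seed=42)[0]
        assert np.array_equal(a, b)


class TestEstimatorContract:
    def test_bootstrap_deterministic_given_seed(self, covid_trial):
        a = dw.LinearModel(draws=25, seed=3).fit(covid_trial)
        b = dw.LinearModel(draws=25, seed=3).fit(covid_trial)
        assert np.array_equal(a.draws_, b.draws_)

    def test_sklearn_clone_and_get_params(self):
        m = dw.HurdleNegBinomial(draws=10, seed=1, zero_terms=["arm"])
        m2 = clone(m)
        assert m2.get_params()["zero_terms"] == ["arm"]

    def test_every_draw_satisfies_invariants(self, fitted):
        fits, _ = fitted
        assert (fits["hurdle_nb"].draws_[:, -1] > 0).all()  # phi
        assert (fits["zoib"].draws_[:, -1] > 0).all()       # phi_b
        assert (fits["linear"].draws_[:, -1] > 0).all()     # sigma
        ncut = fits["cumlogit"].n_categories_ - 1
        cuts = fits["cumlogit"].draws_[:, :ncut]
        assert (np.diff(cuts, axis=1) > 0).all()

    def test_family_support_validation(self, covid_trial, spec_days):
        with pytest.raises(DataError):
            dw.ZeroOneInflatedBeta(draws=1).fit(covid_trial)  # days not in [0,1]
        ordinal = recode_for_family(covid_trial, spec_days, "cumlogit")
        with pytest.raises(DataError):
            dw.HurdleNegBinomial(draws=1).fit(ordinal)  # -1 not allowed

    def test_unknown_family_rejected(self, covid_trial):
        with pytest.raises(dw.ConfigError):
            dw.fit_model("tobit", covid_trial)

    def test_newdata_missing_terms_rejected(self, fitted):
        fits, datasets = fitted
        bad = datasets["linear"].drop(columns=["arm"])
        with pytest.raises(DataError):
            fits["linear"].predict(bad)

    def test_sampler_engine_requires_callable(self, covid_trial):
        with pytest.raises(dw.ConfigError):
            dw.LinearModel(engine="sampler").fit(covid_trial)

    def test_pluggable_sampler_contract(self, covid_trial):
        def fake_sampler(model, mats, y):
            return np.tile(model.point_, (7, 1)) if hasattr(model, "point_") else None

        m = dw.LinearModel(engine="sampler", sampler=fake_sampler).fit(covid_trial)
        assert m.draws_.shape == (7, len(m.point_))
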