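"""Input-model estimation: fits recover simulated truth; samplers preserve
moments; prediction formulas match closed forms."""

import numpy as np
import pytest
from scipy.special import expit, logit

from pacea.errors import EstimationError, NonPositiveDefiniteError
from pacea.estimation import (
    BASE_SCHEMA,
    InputModelSet,
    LogisticModel,
    LogisticParams,
    TwoPartParams,
    WeibullModel,
    WeibullParams,
    annual_transition_probability,
    design_matrix,
    fit_logistic,
    fit_two_part_cost,
    fit_weibull_ph,
    predict_depression_prevalence,
    predict_mean_annual_cost,
    sample_parameter_draw,
)


def simulate_weibull(rng, n, gamma, beta, schema_cols=3, entry_low=40.0, horizon=10.0):
    """Left-truncated Weibull PH data on the age scale."""
    X = np.column_stack(
        [np.ones(n), rng.normal(0, 1, n), rng.integers(0, 2, n).astype(float)]
    )[:, :schema_cols]
    entry = rng.uniform(entry_low, entry_low + 20.0, n)
    scale = np.exp(X @ beta)
    t_event = (entry**gamma + rng.exponential(size=n) / scale) ** (1.0 / gamma)
    censor = entry + horizon
    time = np.minimum(t_event, censor)
    event = t_event <= censor
    return time, event, entry, X


class TestAnnualTransitionProbability:
    def test_zero_scale_gives_zero(self):
        params = WeibullParams(gamma=2.0, beta=np.array([-np.inf]))
        assert annual_transition_probability(params, np.array([[1.0]]), 50.0) == 0.0

    def test_constant_hazard_closed_form(self):
        h = 0.07
        params = WeibullParams(gamma=1.0, beta=np.array([np.log(h)]))
        x = np.array([[1.0]])
        for age in (0.0, 30.0, 85.0):
            assert annual_transition_probability(params, x, age) == pytest.approx(
                1.0 - np.exp(-h)
            )

    def test_quadratic_hazard_direct_arithmetic(self):
        params = WeibullParams(gamma=2.0, beta=np.array([np.log(1e-5)]))
        p = annual_transition_probability(params, np.array([[1.0]]), 50.0)
        assert p == pytest.approx(1.0 - np.exp(-1.01e-3), rel=1e-12)

    def test_negative_age_rejected(self):
        params = WeibullParams(gamma=1.0, beta=np.array([0.0]))
        with pytest.raises(ValueError):
            annual_transition_probability(params, np.array([[1.0]]), -1.0)

    def test_monotone_in_linear_predictor_and_age(self):
        x = np.array([[1.0]])
        params = [WeibullParams(2.0, np.array([b])) for b in (-8.0, -7.0, -6.0)]
        probs = [annual_transition_probability(p, x, 60.0) for p in params]
        assert probs == sorted(probs)
        p_age = [
            annual_transition_probability(WeibullParams(2.0, np.array([-8.0])), x, a)
            for a in (40.0, 60.0, 80.0)
        ]
        assert p_age == sorted(p_age)  # gamma > 1: risk rises with age


class TestPredictions:
    def test_depression_prevalence_limits(self):
        assert predict_depression_prevalence(
            LogisticParams(np.array([0.0])), np.array([1.0])
        ) == pytest.approx(0.5)
        assert predict_depression_prevalence(
            LogisticParams(np.array([-60.0])), np.array([1.0])
        ) == pytest.approx(0.0, abs=1e-20)

    def test_odds_ratio_arithmetic(self):
        # baseline prevalence 10%, most-deprived OR 1.86 -> prevalence 0.1713
        beta = np.array([logit(0.10), np.log(1.86)])
        p = predict_depression_prevalence(LogisticParams(beta), np.array([1.0, 1.0]))
        assert p == pytest.approx(0.2067 / 1.2067, abs=2e-4)
        assert p == pytest.approx(0.1713, abs=2e-4)

    def test_mean_cost_factorization(self):
        params = TwoPartParams(np.array([0.0]), np.array([np.log(100.0)]))
        assert predict_mean_annual_cost(params, np.array([1.0])) == pytest.approx(50.0)
        zero = TwoPartParams(np.array([-40.0]), np.array([np.log(100.0)]))
        assert predict_mean_annual_cost(zero, np.array([1.0])) == pytest.approx(0.0, abs=1e-12)


class TestFitWeibullPH:
    def test_recovers_exponential_truth(self):
        rng = np.random.default_rng(1)
        beta = np.array([np.log(0.05), 0.4, -0.3])
        time, event, entry, X = simulate_weibull(rng, 30_000, 1.0, beta)
        fit = fit_weibull_ph(time, event, entry, X, schema=("intercept", "x1", "x2"))
        se = fit.se()
        assert abs(np.log(fit.gamma) - 0.0) < 3 * se[0]
        for j in range(3):
            assert abs(fit.beta[j] - beta[j]) < 3 * se[1 + j]

    def test_recovers_mortality_style_hazard_ratio(self):
        # binary covariate with HR 1.49 (the most-deprived mortality gradient)
        rng = np.random.default_rng(2)
        n = 30_000
        beta = np.array([np.log(2e-9), np.log(1.49)])
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        entry = rng.uniform(40.0, 60.0, n)
        scale = np.exp(X @ beta)
        t_event = (entry**5.0 + rng.exponential(size=n) / scale) ** (1 / 5.0)
        censor = entry + 10.0
        time = np.minimum(t_event, censor)
        event = t_event <= censor
        fit = fit_weibull_ph(time, event, entry, X, schema=("intercept", "grp"))
        assert abs(fit.beta[1] - np.log(1.49)) < 3 * fit.se()[2]
        assert np.exp(fit.beta[1]) == pytest.approx(1.49, rel=0.12)

    def test_agrees_with_independent_aft_fitter(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(3)
        beta = np.array([np.log(1e-7), 0.5])
        time, event, entry, X = simulate_weibull(rng, 20_000, 4.0, beta, schema_cols=2)
        fit = fit_weibull_ph(time, event, entry, X, schema=("intercept", "x1"))
        df = pd.DataFrame(
            {"T": time, "E": event.astype(int), "x1": X[:, 1], "entry": entry}
        )
        aft = lifelines.WeibullAFTFitter()
        aft.fit(df, duration_col="T", event_col="E", entry_col="entry",
                show_progress=False)
        rho = float(np.exp(aft.params_["rho_"]["Intercept"]))
        beta_aft = float(aft.params_["lambda_"]["x1"])
        # Weibull AFT -> PH: beta_PH = -rho * beta_AFT
        assert fit.gamma == pytest.approx(rho, rel=2e-2)
        assert fit.beta[1] == pytest.approx(-rho * beta_aft, rel=2e-2, abs=5e-3)

    def test_no_events_raises(self):
        rng = np.random.default_rng(4)
        n = 100
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        with pytest.raises(EstimationError, match="no events"):
            fit_weibull_ph(
                np.full(n, 60.0), np.zeros(n, bool), np.full(n, 50.0), X,
                schema=("intercept", "x1"),
            )

    def test_degenerate_design_raises(self):
        rng = np.random.default_rng(5)
        time, event, entry, X = simulate_weibull(rng, 500, 1.0, np.array([np.log(0.1), 0, 0]))
        X[:, 1] = 1.0  # zero variance
        with pytest.raises(EstimationError, match="zero variance"):
            fit_weibull_ph(time, event, entry, X, schema=("intercept", "x1", "x2"))


class TestFitLogistic:
    def test_balanced_null_intercept_near_zero(self):
        rng = np.random.default_rng(6)
        n = 20_000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.random(n) < 0.5
        fit = fit_logistic(y, X, schema=("intercept", "x1"))
        assert abs(fit.beta[0]) < 3 * fit.se()[0] + 1e-3

    def test_recovers_deprivation_odds_ratio(self):
        rng = np.random.default_rng(7)
        n = 50_000
        grp = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), grp])
        p = expit(logit(0.10) + np.log(1.86) * grp)
        y = rng.random(n) < p
        fit = fit_logistic(y, X, schema=("intercept", "grp"))
        assert abs(fit.beta[1] - np.log(1.86)) < 3 * fit.se()[1]

    def test_constant_outcome_raises(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(EstimationError):
            fit_logistic(np.zeros(50), X, schema=("intercept", "x1"))


class TestFitTwoPartCost:
    def test_recovers_gamma_intercept(self):
        rng = np.random.default_rng(8)
        n = 50_000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        nonzero = rng.random(n) < 0.7
        mean_pos = np.exp(6.0 + 0.3 * X[:, 1])
        cost = np.where(nonzero, rng.gamma(1.5, mean_pos / 1.5), 0.0)
        fit = fit_two_part_cost(cost, X, schema=("intercept", "grp"))
        se_gamma = np.sqrt(np.diag(fit.cov_gamma))
        assert abs(fit.beta_gamma[0] - 6.0) < 3 * se_gamma[0]
        assert abs(fit.beta_gamma[1] - 0.3) < 3 * se_gamma[1]

    def test_predicted_mean_matches_empirical(self):
        rng = np.random.default_rng(9)
        n = 100_000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        from scipy.stats import norm

        p_nz = norm.cdf(0.3 + 0.4 * X[:, 1])
        mean_pos = np.exp(5.5 + 0.2 * X[:, 1])
        cost = np.where(rng.random(n) < p_nz, rng.gamma(1.2, mean_pos / 1.2), 0.0)
        fit = fit_two_part_cost(cost, X, schema=("intercept", "grp"))
        pred = predict_mean_annual_cost(fit.mean_params(), X)
        for g in (0.0, 1.0):
            sel = X[:, 1] == g
            assert pred[sel].mean() == pytest.approx(cost[sel].mean(), rel=0.02)

    def test_probit_separates_strata_in_sign(self):
        rng = np.random.default_rng(10)
        n = 4000
        grp = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([np.ones(n), grp])
        cost = np.where(grp == 1, rng.gamma(1.0, 100.0, n), 0.0)
        cost[:10] = 1.0  # avoid perfect separation, keep the gradient extreme
        fit = fit_two_part_cost(cost, X, schema=("intercept", "grp"))
        assert fit.beta_probit[1] > 0

    def test_no_positive_costs_raises(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(EstimationError, match="no positive costs"):
            fit_two_part_cost(np.zeros(20), X, schema=("intercept", "x1"))


def logistic_only_model_set(beta, cov):
    return InputModelSet(
        incidence={}, mortality={},
        depression={"AT_RISK": LogisticModel(np.asarray(beta, float), np.asarray(cov, float),
                                             schema=("a", "b", "c")[: len(beta)])},
        cost={},
    )


class TestParameterSampling:
    def test_zero_covariance_returns_mean_exactly(self, truth_models):
        models = InputModelSet(
            incidence={d: WeibullModel(m.gamma, m.beta, np.zeros_like(m.cov))
                       for d, m in truth_models.incidence.items()},
            mortality={}, depression={}, cost={},
        )
        rng = np.random.default_rng(0)
        draw = sample_parameter_draw(models, rng)
        for d, m in models.incidence.items():
            assert draw.incidence[d].gamma == pytest.approx(m.gamma, rel=1e-14)
            np.testing.assert_array_equal(draw.incidence[d].beta, m.beta)

    def test_scalar_variance_reproduced(self):
        sigma = 0.37
        models = logistic_only_model_set([1.0], [[sigma**2]])
        rng = np.random.default_rng(1)
        draws = np.array(
            [sample_parameter_draw(models, rng).depression["AT_RISK"].beta[0]
             for _ in range(4000)]
        )
        assert draws.std() == pytest.approx(sigma, rel=0.05)
        assert draws.mean() == pytest.approx(1.0, abs=4 * sigma / np.sqrt(4000))

    def test_cholesky_preserves_covariance(self):
        A = np.array([[0.4, 0.1, 0.0], [0.3, 0.2, 0.0], [-0.1, 0.5, 0.3]])
        cov = A @ A.T
        models = logistic_only_model_set([0.0, 1.0, -1.0], cov)
        rng = np.random.default_rng(2)
        sample = np.array(
            [sample_parameter_draw(models, rng).depression["AT_RISK"].beta
             for _ in range(100_000)]
        )
        emp = np.cov(sample.T)
        rel = np.linalg.norm(emp - cov) / np.linalg.norm(cov)
        assert rel < 0.05

    def test_indefinite_covariance_names_model(self):
        models = logistic_only_model_set([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(NonPositiveDefiniteError, match="depression:AT_RISK"):
            sample_parameter_draw(models, np.random.default_rng(3))


class TestSerialization:
    def test_json_round_trip_lossless(self, truth_models, tmp_path):
        path = tmp_path / "models.json"
        truth_models.to_json(path)
        back = InputModelSet.from_json(path)
        for (name_a, a), (name_b, b) in zip(
            truth_models.model_items(), back.model_items()
        ):
            assert name_a == name_b
            np.testing.assert_array_equal(a.mean_vector(), b.mean_vector())
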