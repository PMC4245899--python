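"""Input-model estimation for the Markov model.

Three regression families supply every transition input:

* **Weibull proportional hazards** for disease incidence and state-specific
  mortality.  The time scale is attained age ``a`` (years) with left
  truncation at the age of entry to the risk set; the cumulative hazard is
  ``H(a) = exp(x @ beta) * a**gamma`` so hazard ratios are ``exp(beta)``.
  The annual transition probability from age ``a`` is
  ``p = 1 - exp(-(H(a+1) - H(a)))``.
* **Logistic regression** for the annual prevalence of comorbid depression.
* **Two-part cost model** for annual health-care costs: a probit for the
  probability of any (non-zero) cost times a gamma GLM with log link for the
  mean positive cost, so the predicted mean is ``Phi(x@b1) * exp(x@b2)``.

Covariates are an intercept, age centred at 50 years, a female indicator and
indicator variables for deprivation quintiles 2-5 (quintile 1, least
deprived, is the reference).  Cost models additionally carry a depressed
indicator.

Parameter uncertainty for the probabilistic sensitivity analysis is
propagated by sampling ``theta = mean + L @ z`` with ``L`` the (lower)
Cholesky factor of each model's variance-covariance matrix and ``z``
standard normal; the Weibull shape enters the sampled vector as
``log(gamma)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .errors import EstimationError, NonPositiveDefiniteError
from .states import DISEASES

BASE_SCHEMA: tuple[str, ...] = ("intercept", "age_c", "female", "q2", "q3", "q4", "q5")
COST_SCHEMA: tuple[str, ...] = BASE_SCHEMA + ("depressed",)

#: Mortality / depression / cost model classes: healthy plus each single condition.
STATE_CLASSES: tuple[str, ...] = ("AT_RISK",) + DISEASES

AGE_CENTER = 50.0


def design_matrix(
    age: np.ndarray | float,
    female: np.ndarray | float,
    quintile: np.ndarray | int,
    depressed: np.ndarray | float | None = None,
) -> np.ndarray:
    """Build the design matrix for the shared covariate schema.

    ``quintile`` is coded 1-5 (1 = least deprived, the reference level).
    When ``depressed`` is given the matrix follows ``COST_SCHEMA``.
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    female = np.broadcast_to(np.asarray(female, dtype=float), age.shape)
    quintile = np.broadcast_to(np.asarray(quintile, dtype=int), age.shape)
    cols = [
        np.ones_like(age),
        age - AGE_CENTER,
        female,
        (quintile == 2).astype(float),
        (quintile == 3).astype(float),
        (quintile == 4).astype(float),
        (quintile == 5).astype(float),
    ]
    if depressed is not None:
        cols.append(np.broadcast_to(np.asarray(depressed, dtype=float), age.shape))
    return np.column_stack(cols)


def design_vector(age: float, female: bool, quintile: int, depressed: bool | None = None) -> np.ndarray:
    return design_matrix(age, float(female), quintile, None if depressed is None else float(depressed))[0]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class WeibullParams:
    """One concrete Weibull PH parameter point (a PSA draw or the mean)."""

    gamma: float
    beta: np.ndarray

    def one_year_cumhaz(self, x: np.ndarray, age: np.ndarray | float) -> np.ndarray:
        """Cumulative hazard accumulated between ages ``a`` and ``a+1``.

        Evaluated as ``exp(eta + g*log a) * expm1(g*log1p(1/a))`` so extreme
        sampled shapes overflow to +inf (annual probability 1) instead of
        producing inf - inf NaNs.
        """
        age = np.atleast_1d(np.asarray(age, dtype=float))
        if np.any(age < 0):
            raise ValueError("age must be non-negative")
        eta = np.asarray(x, dtype=float) @ self.beta
        safe_age = np.where(age > 0, age, 1.0)
        with np.errstate(over="ignore"):
            out = np.exp(eta + self.gamma * np.log(safe_age)) * np.expm1(
                self.gamma * np.log1p(1.0 / safe_age)
            )
            out = np.where(age > 0, out, np.exp(eta))  # H(1) - H(0) = exp(eta)
        return out


@dataclass
class LogisticParams:
    beta: np.ndarray

    def prevalence(self, x: np.ndarray) -> np.ndarray:
        return expit(np.asarray(x, dtype=float) @ self.beta)


@dataclass
class TwoPartParams:
    beta_probit: np.ndarray
    beta_gamma: np.ndarray

    def mean_cost(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return norm.cdf(x @ self.beta_probit) * np.exp(x @ self.beta_gamma)


def annual_transition_probability(
    params: WeibullParams, x: np.ndarray, age: np.ndarray | float
) -> np.ndarray:
    """Annual probability ``1 - exp(-(H(a+1) - H(a)))`` of the modelled event."""
    return -np.expm1(-params.one_year_cumhaz(x, age))


def predict_depression_prevalence(params: LogisticParams, x: np.ndarray) -> np.ndarray:
    return params.prevalence(x)


def predict_mean_annual_cost(params: TwoPartParams, x: np.ndarray) -> np.ndarray:
    return params.mean_cost(x)


# ---------------------------------------------------------------------------
# Fitted (or configured-truth) models: mean vector + covariance
# ---------------------------------------------------------------------------


@dataclass
class WeibullModel:
    """Weibull PH model: shape, coefficients and joint covariance.

    The parameter vector ordering is ``(log gamma, *beta)``; ``cov`` is the
    covariance of that full vector.
    """

    gamma: float
    beta: np.ndarray
    cov: np.ndarray
    schema: tuple[str, ...] = BASE_SCHEMA

    def mean_vector(self) -> np.ndarray:
        return np.concatenate(([np.log(self.gamma)], self.beta))

    def params_from_vector(self, theta: np.ndarray) -> WeibullParams:
        return WeibullParams(gamma=float(np.exp(theta[0])), beta=np.asarray(theta[1:], dtype=float))

    def mean_params(self) -> WeibullParams:
        return WeibullParams(gamma=self.gamma, beta=self.beta.copy())

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class LogisticModel:
    beta: np.ndarray
    cov: np.ndarray
    schema: tuple[str, ...] = BASE_SCHEMA

    def mean_vector(self) -> np.ndarray:
        return np.asarray(self.beta, dtype=float)

    def params_from_vector(self, theta: np.ndarray) -> LogisticParams:
        return LogisticParams(beta=np.asarray(theta, dtype=float))

    def mean_params(self) -> LogisticParams:
        return LogisticParams(beta=self.beta.copy())

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class TwoPartCostModel:
    beta_probit: np.ndarray
    cov_probit: np.ndarray
    beta_gamma: np.ndarray
    cov_gamma: np.ndarray
    gamma_shape: float = 1.0  # dispersion of positive costs, used for simulation
    schema: tuple[str, ...] = COST_SCHEMA

    def mean_vector(self) -> np.ndarray:
        return np.concatenate([self.beta_probit, self.beta_gamma])

    def params_from_vector(self, theta: np.ndarray) -> TwoPartParams:
        k = len(self.beta_probit)
        return TwoPartParams(
            beta_probit=np.asarray(theta[:k], dtype=float),
            beta_gamma=np.asarray(theta[k:], dtype=float),
        )

    def mean_params(self) -> TwoPartParams:
        return TwoPartParams(self.beta_probit.copy(), self.beta_gamma.copy())

    def cov_block(self) -> np.ndarray:
        k = len(self.beta_probit)
        m = len(self.beta_gamma)
        cov = np.zeros((k + m, k + m))
        cov[:k, :k] = self.cov_probit
        cov[k:, k:] = self.cov_gamma
        return cov


@dataclass
class InputModelSet:
    """The full set of input models feeding the Markov engine.

    ``incidence`` is keyed by disease; ``mortality``, ``depression`` and
    ``cost`` by state class (healthy "AT_RISK" plus each single condition).
    Multi-condition states are composed additively on the log-hazard / logit
    / linear-predictor scale from the single-condition increments.
    """

    incidence: dict[str, WeibullModel]
    mortality: dict[str, WeibullModel]
    depression: dict[str, LogisticModel]
    cost: dict[str, TwoPartCostModel]
    meta: dict = field(default_factory=dict)

    def model_items(self) -> Iterable[tuple[str, object]]:
        for d, m in self.incidence.items():
            yield f"incidence:{d}", m
        for c, m in self.mortality.items():
            yield f"mortality:{c}", m
        for c, m in self.depression.items():
            yield f"depression:{c}", m
        for c, m in self.cost.items():
            yield f"cost:{c}", m

    def mean_draw(self) -> "ParameterDraw":
        return ParameterDraw(
            incidence={d: m.mean_params() for d, m in self.incidence.items()},
            mortality={c: m.mean_params() for c, m in self.mortality.items()},
            depression={c: m.mean_params() for c, m in self.depression.items()},
            cost={c: m.mean_params() for c, m in self.cost.items()},
        )

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path) -> None:
        def arr(a):
            return np.asarray(a, dtype=float).tolist()

        payload = {
            "incidence": {
                d: {"gamma": m.gamma, "beta": arr(m.beta), "cov": arr(m.cov), "schema": list(m.schema)}
                for d, m in self.incidence.items()
            },
            "mortality": {
                c: {"gamma": m.gamma, "beta": arr(m.beta), "cov": arr(m.cov), "schema": list(m.schema)}
                for c, m in self.mortality.items()
            },
            "depression": {
                c: {"beta": arr(m.beta), "cov": arr(m.cov), "schema": list(m.schema)}
                for c, m in self.depression.items()
            },
            "cost": {
                c: {
                    "beta_probit": arr(m.beta_probit),
                    "cov_probit": arr(m.cov_probit),
                    "beta_gamma": arr(m.beta_gamma),
                    "cov_gamma": arr(m.cov_gamma),
                    "gamma_shape": m.gamma_shape,
                    "schema": list(m.schema),
                }
                for c, m in self.cost.items()
            },
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "InputModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        A = lambda a: np.asarray(a, dtype=float)  # noqa: E731
        return cls(
            incidence={
                d: WeibullModel(v["gamma"], A(v["beta"]), A(v["cov"]), tuple(v["schema"]))
                for d, v in payload["incidence"].items()
            },
            mortality={
                c: WeibullModel(v["gamma"], A(v["beta"]), A(v["cov"]), tuple(v["schema"]))
                for c, v in payload["mortality"].items()
            },
            depression={
                c: LogisticModel(A(v["beta"]), A(v["cov"]), tuple(v["schema"]))
                for c, v in payload["depression"].items()
            },
            cost={
                c: TwoPartCostModel(
                    A(v["beta_probit"]),
                    A(v["cov_probit"]),
                    A(v["beta_gamma"]),
                    A(v["cov_gamma"]),
                    v.get("gamma_shape", 1.0),
                    tuple(v["schema"]),
                )
                for c, v in payload["cost"].items()
            },
            meta=payload.get("meta", {}),
        )


@dataclass
class ParameterDraw:
    """One joint sampled parameter point for all input models."""

    incidence: dict[str, WeibullParams]
    mortality: dict[str, WeibullParams]
    depression: dict[str, LogisticParams]
    cost: dict[str, TwoPartParams]
    sim_index: int = 0


def _psd_factor(cov: np.ndarray, name: str) -> np.ndarray:
    """Lower-triangular-like factor ``L`` with ``L @ L.T == cov``.

    Uses the Cholesky factor when the matrix is positive definite and an
    eigen-decomposition square root for semi-definite matrices (e.g. zero
    rows for fixed parameters).  Raises for genuinely indefinite input.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.size == 0 or not np.any(cov):
        return np.zeros_like(cov)
    if not np.allclose(cov, cov.T, rtol=1e-10, atol=1e-12):
        raise NonPositiveDefiniteError(f"covariance of model '{name}' is not symmetric")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        tol = -1e-8 * max(1.0, float(np.max(np.abs(w))))
        if np.min(w) < tol:
            raise NonPositiveDefiniteError(
                f"covariance of model '{name}' is not positive semi-definite"
            ) from None
        return v * np.sqrt(np.clip(w, 0.0, None))


def sample_parameter_draw(
    models: InputModelSet, rng: np.random.Generator, sim_index: int = 0
) -> ParameterDraw:
    """Draw one correlated parameter set: ``theta = mean + L @ z`` per model."""

    def draw_one(model, cov):
        mean = model.mean_vector()
        L = _psd_factor(cov, name)
        z = rng.standard_normal(len(mean))
        return model.params_from_vector(mean + L @ z)

    out: dict[str, dict] = {"incidence": {}, "mortality": {}, "depression": {}, "cost": {}}
    for name, model in models.model_items():
        family, key = name.split(":")
        cov = model.cov_block() if isinstance(model, TwoPartCostModel) else model.cov
        out[family][key] = draw_one(model, cov)
    return ParameterDraw(sim_index=sim_index, **out)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _check_design(X: np.ndarray, schema: tuple[str, ...]) -> None:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(schema):
        raise EstimationError(f"design matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, schema has {len(schema)}")
    for j, col in enumerate(schema):
        if col == "intercept":
            continue
        if np.ptp(X[:, j]) == 0.0:
            raise EstimationError(f"covariate '{col}' has zero variance")


def fit_weibull_ph(
    time: np.ndarray,
    event: np.ndarray,
    entry: np.ndarray,
    X: np.ndarray,
    schema: tuple[str, ...] = BASE_SCHEMA,
) -> WeibullModel:
    """Maximum-likelihood Weibull PH fit with left truncation.

    ``time`` is the age at event or censoring, ``entry`` the age at which the
    subject entered the risk set, ``event`` the event indicator.  The
    covariance is the inverse observed information over ``(log gamma, beta)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    entry = np.asarray(entry, dtype=float)
    X = np.asarray(X, dtype=float)
    if event.sum() == 0:
        raise EstimationError("no events observed; cannot fit Weibull model")
    if np.any(time <= entry):
        raise EstimationError("all observation times must exceed the entry age")
    if np.any(entry < 0):
        raise EstimationError("entry ages must be non-negative")
    _check_design(X, schema)

    # Fit on a rescaled time axis t/t_ref: with H = exp(x@b)*t^g the shape
    # and intercept are near-collinear (b0 ~ -g*log t_ref), so optimise
    # b0' = b0 + g*log(t_ref) instead and map back afterwards.
    t_ref = float(np.median(time))
    ts = time / t_ref
    es = entry / t_ref
    logt = np.log(ts)
    log_entry = np.log(np.where(es > 0, es, 1.0))
    delta = event.astype(float)
    n_events = delta.sum()

    def unpack(theta):
        return np.exp(theta[0]), theta[1:]

    def neg_loglik(theta):
        gamma, beta = unpack(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            eta = X @ beta
            tg = ts**gamma
            ag = np.where(es > 0, es**gamma, 0.0)
            ll = np.sum(delta * (np.log(gamma) + (gamma - 1.0) * logt + eta)) - np.sum(
                np.exp(eta) * (tg - ag)
            )
        return -ll if np.isfinite(ll) else np.inf

    def neg_grad(theta):
        gamma, beta = unpack(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            eta = X @ beta
            w = np.exp(eta)
            tg = ts**gamma
            ag = np.where(es > 0, es**gamma, 0.0)
            d_beta = X.T @ (delta - w * (tg - ag))
            d_gamma = np.sum(delta * (1.0 / gamma + logt)) - np.sum(
                w * (tg * logt - ag * log_entry)
            )
            g = -np.concatenate(([d_gamma * gamma], d_beta))  # chain rule, log gamma
        return np.where(np.isfinite(g), g, 0.0)

    # starting values: per-gamma profile of the intercept, best of a grid
    p = X.shape[1]
    bounds = [(-4.0, 4.0)] + [(None, None)] * p

    def start_for(gamma0):
        theta = np.zeros(1 + p)
        theta[0] = np.log(gamma0)
        with np.errstate(over="ignore"):
            denom = np.sum(ts**gamma0 - np.where(es > 0, es**gamma0, 0.0))
        theta[1] = np.log(max(n_events, 1.0) / max(denom, 1e-300))
        return theta

    starts = sorted((start_for(g0) for g0 in (1.0, 2.0, 5.0, 8.0)), key=neg_loglik)
    res = None
    for theta0 in starts:
        cand = minimize(neg_loglik, theta0, jac=neg_grad, method="L-BFGS-B",
                        bounds=bounds)
        if res is None or cand.fun < res.fun:
            res = cand
        if cand.success:
            res = cand if cand.fun <= res.fun else res
            break
    if not np.isfinite(res.fun):
        raise EstimationError(f"Weibull fit did not converge: {res.message}")
    theta = res.x

    # observed information via central differences of the analytic gradient
    H = np.zeros((1 + p, 1 + p))
    for j in range(1 + p):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (neg_grad(tp) - neg_grad(tm)) / (2.0 * h)
    H = 0.5 * (H + H.T)
    try:
        cov_s = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular observed information in Weibull fit") from exc

    gamma, beta_s = unpack(theta)
    # map back to the unscaled axis: b0 = b0' - g*log(t_ref); J is the
    # identity apart from d b0 / d log g = -g log t_ref
    beta = beta_s.copy()
    beta[0] = beta_s[0] - gamma * np.log(t_ref)
    J = np.eye(1 + p)
    J[1, 0] = -gamma * np.log(t_ref)
    cov = J @ cov_s @ J.T
    return WeibullModel(gamma=float(gamma), beta=np.asarray(beta), cov=cov, schema=schema)


def fit_logistic(
    y: np.ndarray, X: np.ndarray, schema: tuple[str, ...] = BASE_SCHEMA
) -> LogisticModel:
    """Logistic regression via statsmodels with its estimated covariance."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise EstimationError("outcome is constant; logistic model is not identified")
    _check_design(X, schema)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation, singular design, ...
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    return LogisticModel(beta=np.asarray(fit.params), cov=np.asarray(fit.cov_params()), schema=schema)


def fit_two_part_cost(
    costs: np.ndarray, X: np.ndarray, schema: tuple[str, ...] = COST_SCHEMA
) -> TwoPartCostModel:
    """Two-part annual-cost model: probit on cost>0, gamma GLM (log link) on
    positive costs."""
    import statsmodels.api as sm

    costs = np.asarray(costs, dtype=float)
    if np.any(costs < 0):
        raise EstimationError("costs must be non-negative")
    positive = costs > 0
    if positive.sum() == 0:
        raise EstimationError("no positive costs; cannot fit two-part model")
    _check_design(X, schema)
    try:
        with np.errstate(all="ignore"):
            probit = sm.Probit(positive.astype(float), X).fit(disp=0, maxiter=200)
            glm = sm.GLM(
                costs[positive],
                np.asarray(X)[positive],
                family=sm.families.Gamma(sm.families.links.Log()),
            ).fit()
    except Exception as exc:
        raise EstimationError(f"two-part cost fit failed: {exc}") from exc
    return TwoPartCostModel(
        beta_probit=np.asarray(probit.params),
        cov_probit=np.asarray(probit.cov_params()),
        beta_gamma=np.asarray(glm.params),
        cov_gamma=np.asarray(glm.cov_params()),
        gamma_shape=float(1.0 / glm.scale),
        schema=schema,
    )


def fit_logistic_depression(
    annual_records, covariates: tuple[str, ...] = BASE_SCHEMA
) -> LogisticModel:
    """Fit the annual depression-prevalence logistic model from a person-year
    table with columns ``age, female, quintile, depressed``."""
    X = design_matrix(
        annual_records["age"].to_numpy(),
        annual_records["female"].to_numpy(),
        annual_records["quintile"].to_numpy(),
    )
    return fit_logistic(annual_records["depressed"].to_numpy(), X, covariates)


def fit_two_part_cost_table(
    annual_records, covariates: tuple[str, ...] = COST_SCHEMA
) -> TwoPartCostModel:
    """Fit the two-part cost model from a person-year table with columns
    ``age, female, quintile, depressed, cost``."""
    X = design_matrix(
        annual_records["age"].to_numpy(),
        annual_records["female"].to_numpy(),
        annual_records["quintile"].to_numpy(),
        annual_records["depressed"].to_numpy(),
    )
    return fit_two_part_cost(annual_records["cost"].to_numpy(), X, covariates)


# ---------------------------------------------------------------------------
# Composition across condition subsets (additive-on-log-scale rule)
# ---------------------------------------------------------------------------


def composed_mortality_params(
    draw: ParameterDraw, mask_diseases: tuple[str, ...]
) -> WeibullParams:
    """Mortality Weibull parameters for a condition subset.

    Log cumulative hazards compose additively in the single-condition
    increments over the healthy baseline:
    ``log H_D(a) = log H_AR(a) + sum_d [log H_d(a) - log H_AR(a)]``.
    Because each term is ``log s + gamma log a``, the composed model is
    again Weibull with additively composed shape and coefficients.
    """
    base = draw.mortality["AT_RISK"]
    gamma = base.gamma
    beta = base.beta.copy()
    for d in mask_diseases:
        gamma += draw.mortality[d].gamma - base.gamma
        beta = beta + (draw.mortality[d].beta - base.beta)
    return WeibullParams(gamma=gamma, beta=beta)


def composed_depression_logit(
    draw: ParameterDraw, mask_diseases: tuple[str, ...], x: np.ndarray
) -> np.ndarray:
    """Depression-prevalence logit for a condition subset (additive rule)."""
    x = np.asarray(x, dtype=float)
    base = x @ draw.depression["AT_RISK"].beta
    out = base.copy() if hasattr(base, "copy") else float(base)
    for d in mask_diseases:
        out = out + (x @ draw.depression[d].beta - base)
    return out


def composed_cost_params(
    draw: ParameterDraw, mask_diseases: tuple[str, ...]
) -> TwoPartParams:
    """Two-part cost coefficients for a condition subset (additive rule)."""
    base = draw.cost["AT_RISK"]
    bp = base.beta_probit.copy()
    bg = base.beta_gamma.copy()
    for d in mask_diseases:
        bp = bp + (draw.cost[d].beta_probit - base.beta_probit)
        bg = bg + (draw.cost[d].beta_gamma - base.beta_gamma)
    return TwoPartParams(beta_probit=bp, beta_gamma=bg)
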