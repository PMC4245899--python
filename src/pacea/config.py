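"""Configuration loading and default study inputs.

The default configuration ships with the package
(``pacea/configs/truth_default.yaml``) and carries:

* the synthetic-truth parameters of the three input-model families, with
  deprivation-quintile hazard/odds-ratio gradients;
* the entry-population demographics (quintile shares, sex split, entry-age
  means);
* the population activity distribution anchors and the per-disease relative
  risks for inactivity;
* the state utility values.

``build_truth_models`` converts the configured truth into an
:class:`~pacea.estimation.InputModelSet` with a diagonal covariance built
from the configured standard errors, so the same object can drive both the
registry simulator and the probabilistic Markov model.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .economics import EconParams, UtilityTable
from .errors import ConfigurationError
from .estimation import (
    BASE_SCHEMA,
    COST_SCHEMA,
    InputModelSet,
    LogisticModel,
    TwoPartCostModel,
    WeibullModel,
)
from .intervention import AGE_BANDS, ActivityDistribution, InterventionSpec, RelativeRiskSet
from .registry import Demographics
from .states import DISEASES


def load_default_config() -> dict:
    """Load the packaged default configuration."""
    with resources.files("pacea.configs").joinpath("truth_default.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML configuration file, or the packaged default."""
    if path is None:
        return load_default_config()
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"configuration file not found: {p}")
    with open(p) as fh:
        return yaml.safe_load(fh)


def _beta_from(intercept: float, age: float, female: float, quintile_ratios) -> np.ndarray:
    """Coefficient vector on the shared schema from ratio-style config."""
    qr = np.asarray(quintile_ratios, dtype=float)
    if len(qr) != 5 or abs(qr[0] - 1.0) > 1e-12:
        raise ConfigurationError("quintile ratios must have 5 entries with reference 1.0")
    if np.any(qr <= 0):
        raise ConfigurationError("quintile ratios must be positive")
    return np.array([intercept, age, female, *np.log(qr[1:])])


def _diag_cov(n: int, intercept_se: float, age_se: float, coef_se: float,
              lead_se: float | None = None) -> np.ndarray:
    """Diagonal covariance for a coefficient vector on the shared schema.

    ``lead_se`` prepends an extra leading parameter (log shape for Weibull)."""
    ses = [intercept_se, age_se] + [coef_se] * (n - 2)
    if lead_se is not None:
        ses = [lead_se] + ses
    return np.diag(np.square(ses))


def build_truth_models(config: dict | None = None) -> InputModelSet:
    """Assemble the configured-truth input models with diagonal covariance."""
    cfg = config or load_default_config()
    unc = cfg["uncertainty"]
    p = len(BASE_SCHEMA)

    incidence = {}
    for d in DISEASES:
        c = cfg["weibull_incidence"][d]
        if c["shape"] <= 0:
            raise ConfigurationError(f"Weibull shape for {d} must be positive")
        incidence[d] = WeibullModel(
            gamma=float(c["shape"]),
            beta=_beta_from(c["log_scale"], c["age"], c["female"], c["quintile_hr"]),
            cov=_diag_cov(p, unc["intercept_se"], unc["age_se"], unc["coef_se"],
                          lead_se=unc["log_shape_se"]),
        )

    mort_cfg = cfg["weibull_mortality"]
    shape = float(mort_cfg["shape"])
    if shape <= 0:
        raise ConfigurationError("mortality Weibull shape must be positive")
    ar = mort_cfg["AT_RISK"]
    mortality = {
        "AT_RISK": WeibullModel(
            gamma=shape,
            beta=_beta_from(ar["log_scale"], ar["age"], ar["female"], ar["quintile_hr"]),
            cov=_diag_cov(p, unc["intercept_se"], unc["age_se"], unc["coef_se"],
                          lead_se=unc["log_shape_se"]),
        )
    }
    for d in DISEASES:
        c = mort_cfg[d]
        mortality[d] = WeibullModel(
            gamma=shape,
            beta=_beta_from(ar["log_scale"] + c["log_hr"], c["age"], c["female"],
                            c["quintile_hr"]),
            cov=_diag_cov(p, unc["intercept_se"], unc["age_se"], unc["coef_se"],
                          lead_se=unc["log_shape_se"]),
        )

    depression = {}
    for cls in ("AT_RISK", *DISEASES):
        c = cfg["depression_logistic"][cls]
        depression[cls] = LogisticModel(
            beta=_beta_from(c["intercept"], c["age"], c["female"], c["quintile_or"]),
            cov=_diag_cov(p, unc["intercept_se"], unc["age_se"], unc["coef_se"]),
        )

    cost_cfg = cfg["cost_two_part"]
    ar_probit = cost_cfg["AT_RISK"]["probit"]
    ar_gamma = cost_cfg["AT_RISK"]["gamma"]

    def cost_beta(part: dict, shift: float = 0.0) -> np.ndarray:
        q = np.asarray(part["quintile"], dtype=float)
        return np.array([part["intercept"] + shift, part["age"], part["female"],
                         *q[1:], part["depressed"]])

    pc = len(COST_SCHEMA)
    cost = {}
    for cls in ("AT_RISK", *DISEASES):
        p_shift = 0.0 if cls == "AT_RISK" else float(cost_cfg[cls]["probit_shift"])
        g_shift = 0.0 if cls == "AT_RISK" else float(cost_cfg[cls]["gamma_shift"])
        cov = _diag_cov(pc, unc["intercept_se"], unc["age_se"], unc["coef_se"])
        cost[cls] = TwoPartCostModel(
            beta_probit=cost_beta(ar_probit, p_shift),
            cov_probit=cov,
            beta_gamma=cost_beta(ar_gamma, g_shift),
            cov_gamma=cov.copy(),
            gamma_shape=float(cost_cfg["gamma_shape"]),
        )

    return InputModelSet(
        incidence=incidence, mortality=mortality, depression=depression, cost=cost,
        meta={"source": "configured truth"},
    )


def build_demographics(config: dict | None = None) -> Demographics:
    cfg = (config or load_default_config())["demographics"]
    male = np.asarray(cfg["male_counts"], dtype=float)
    female = np.asarray(cfg["female_counts"], dtype=float)
    total = male + female
    return Demographics(
        quintile_shares=total / total.sum(),
        female_share=female / total,
        male_mean_age=np.asarray(cfg["male_mean_age"], dtype=float),
        female_mean_age=np.asarray(cfg["female_mean_age"], dtype=float),
        age_sd=float(cfg["age_sd"]),
        age_min=float(cfg["age_min"]),
        age_max=float(cfg["age_max"]),
    )


def build_activity_distribution(config: dict | None = None) -> ActivityDistribution:
    """Default three-category activity distribution per sex/band/quintile.

    Anchored on the configured age-standardised inactivity prevalences per
    sex and quintile (which apply at the mid-age band) with a linear age
    gradient: inactivity rises and the active share falls with age.  The
    active (5 days/week) share varies by age but not deprivation: the
    deprivation gradient lives in the split between inactive and
    insufficiently active, so combining those two categories largely
    removes the inequality.
    """
    cfg = (config or load_default_config())["activity"]
    anchors = {
        0: np.asarray(cfg["male_inactive_pct"], dtype=float) / 100.0,
        1: np.asarray(cfg["female_inactive_pct"], dtype=float) / 100.0,
    }
    rows = []
    for f in (0, 1):
        for b in range(len(AGE_BANDS)):
            for q in range(1, 6):
                p_in = float(np.clip(anchors[f][q - 1] * (0.70 + 0.10 * b), 0.02, 0.90))
                p_act = float(np.clip(0.38 - 0.03 * b, 0.02, 0.95 - p_in))
                rows.append(
                    {
                        "female": f,
                        "age_band": b,
                        "quintile": q,
                        "p_inactive": p_in,
                        "p_insufficient": 1.0 - p_in - p_act,
                        "p_active": p_act,
                    }
                )
    return ActivityDistribution(pd.DataFrame(rows))


def activity_distribution_from_csv(path) -> ActivityDistribution:
    return ActivityDistribution(pd.read_csv(path))


def build_relative_risks(config: dict | None = None) -> RelativeRiskSet:
    cfg = (config or load_default_config())["relative_risks"]
    return RelativeRiskSet(
        rr={d: (float(cfg[d]["inactive"]), float(cfg[d]["insufficient"])) for d in DISEASES}
    )


def build_utilities(config: dict | None = None) -> UtilityTable:
    cfg = (config or load_default_config())["utilities"]
    return UtilityTable(
        at_risk=float(cfg["at_risk"]),
        disease={d: float(cfg[d]) for d in DISEASES},
        depression_multiplier=float(cfg["depression_multiplier"]),
    )


def build_intervention_spec(overrides: dict | None = None) -> InterventionSpec:
    """Intervention specification with optional scenario overrides."""
    kwargs = {}
    if overrides:
        allowed = {"or_active", "or_interval", "duration", "unit_cost",
                   "screening_fraction", "attenuation", "cost_multiplier"}
        unknown = set(overrides) - allowed
        if unknown:
            raise ConfigurationError(f"unknown intervention settings: {sorted(unknown)}")
        kwargs = dict(overrides)
        if "or_interval" in kwargs:
            kwargs["or_interval"] = tuple(kwargs["or_interval"])
    return InterventionSpec(**kwargs)


def build_econ_params(overrides: dict | None = None) -> EconParams:
    kwargs = dict(overrides or {})
    if "ceac_thresholds" in kwargs:
        kwargs["ceac_thresholds"] = np.asarray(kwargs["ceac_thresholds"], dtype=float)
    return EconParams(**kwargs)
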