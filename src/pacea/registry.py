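"""Synthetic registry and activity-survey generation.

Emulates the two data sources the analysis needs, with known ground truth:

* a primary-care registry of adults with entry age, sex, deprivation
  quintile, time-to-event follow-up for four chronic conditions and death,
  annual depression indicators and annual health-care costs (with a point
  mass at zero);
* a population activity survey with three activity categories per sex,
  10-year age band and deprivation quintile.

Event histories are simulated exactly from the Weibull proportional-hazards
truth on the attained-age time scale with left truncation at the entry age:
conditional on being event-free at age ``a`` the event age solves
``H(T) = H(a) + E`` with ``E ~ Exp(1)``.  Mortality hazards depend on the
current condition set (additive-on-log-scale composition); incidence
hazards of the four conditions are mutually independent.  Depression and
costs are drawn independently each year given the state occupied at the
start of the year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, truncnorm

from .errors import ConfigurationError
from .estimation import (
    InputModelSet,
    ParameterDraw,
    composed_cost_params,
    composed_depression_logit,
    composed_mortality_params,
    design_matrix,
)
from .intervention import AGE_BANDS, ActivityDistribution
from .states import DISEASES, mask_diseases


@dataclass
class Demographics:
    """Entry-population description: quintile shares, sex split and entry ages."""

    quintile_shares: np.ndarray  # (5,) probabilities, least -> most deprived
    female_share: np.ndarray  # (5,) probability female per quintile
    male_mean_age: np.ndarray  # (5,)
    female_mean_age: np.ndarray  # (5,)
    age_sd: float = 10.0
    age_min: float = 18.0
    age_max: float = 90.0

    def __post_init__(self) -> None:
        self.quintile_shares = np.asarray(self.quintile_shares, dtype=float)
        self.female_share = np.broadcast_to(
            np.asarray(self.female_share, dtype=float), (5,)
        ).copy()
        self.male_mean_age = np.asarray(self.male_mean_age, dtype=float)
        self.female_mean_age = np.asarray(self.female_mean_age, dtype=float)
        if abs(self.quintile_shares.sum() - 1.0) > 1e-9 or np.any(self.quintile_shares < 0):
            raise ConfigurationError("quintile shares must be non-negative and sum to 1")
        if np.any(self.female_share < 0) or np.any(self.female_share > 1):
            raise ConfigurationError("female share must lie in [0, 1]")
        if not self.age_min < self.age_max:
            raise ConfigurationError("age bounds must satisfy min < max")
        if self.age_sd <= 0:
            raise ConfigurationError("age SD must be positive")

    def mean_age(self, female: bool, quintile: int) -> float:
        return float((self.female_mean_age if female else self.male_mean_age)[quintile - 1])

    def integer_age_weights(self, female: bool, quintile: int) -> tuple[np.ndarray, np.ndarray]:
        """Entry weights over integer single years of age.

        Discretises the truncated-normal entry-age distribution onto integer
        ages (mass of [a, a+1)), normalised over the configured bounds.
        """
        mu = self.mean_age(female, quintile)
        sd = self.age_sd
        ages = np.arange(int(np.floor(self.age_min)), int(np.ceil(self.age_max)))
        upper = norm.cdf((ages + 1 - mu) / sd)
        lower = norm.cdf((ages - mu) / sd)
        w = upper - lower
        return ages, w / w.sum()


def generate_cohort(n: int, seed: int, demographics: Demographics) -> pd.DataFrame:
    """Draw an entry cohort: id, female, quintile, entry_age.

    Ages are truncated-normal per sex x quintile stratum within the
    configured bounds; reproducible for a fixed seed.
    """
    if n < 0:
        raise ConfigurationError("n must be non-negative")
    rng = np.random.default_rng(seed)
    quintile = rng.choice(np.arange(1, 6), size=n, p=demographics.quintile_shares)
    female = rng.random(n) < demographics.female_share[quintile - 1]
    entry_age = np.empty(n)
    for q in range(1, 6):
        for f in (False, True):
            sel = (quintile == q) & (female == f)
            if not sel.any():
                continue
            mu = demographics.mean_age(f, q)
            sd = demographics.age_sd
            a = (demographics.age_min - mu) / sd
            b = (demographics.age_max - mu) / sd
            entry_age[sel] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=sel.sum(), random_state=rng)
    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "female": female.astype(np.int8),
            "quintile": quintile.astype(np.int8),
            "entry_age": entry_age,
        }
    )


@dataclass
class RegistryTable:
    """Simulated registry: one events row per person plus a person-year table.

    ``events`` columns: id, female, quintile, entry_age, end_age, plus per
    condition ``age_<D>`` / ``event_<D>`` and ``age_death`` / ``event_death``
    (ages are censoring ages when the indicator is 0).
    ``person_years`` columns: id, year, age, female, quintile, mask,
    depressed, cost.
    """

    events: pd.DataFrame
    person_years: pd.DataFrame

    def to_csv(self, events_path, person_years_path) -> None:
        self.events.to_csv(events_path, index=False)
        self.person_years.to_csv(person_years_path, index=False)


def _conditional_weibull_sample(
    rng: np.random.Generator, gamma: np.ndarray, scale: np.ndarray, age: np.ndarray
) -> np.ndarray:
    """Event age given event-free at ``age``: H(T) = H(age) + Exp(1)."""
    e = rng.exponential(size=len(age))
    return (age**gamma + e / scale) ** (1.0 / gamma)


def simulate_event_histories(
    cohort: pd.DataFrame,
    truth: InputModelSet | ParameterDraw,
    horizon: float,
    seed: int,
) -> RegistryTable:
    """Simulate follow-up of ``cohort`` under ``truth`` for ``horizon`` years."""
    if horizon <= 0:
        raise ConfigurationError("horizon must be positive")
    draw = truth.mean_draw() if isinstance(truth, InputModelSet) else truth
    rng = np.random.default_rng(seed)
    n = len(cohort)

    entry = cohort["entry_age"].to_numpy(dtype=float)
    female = cohort["female"].to_numpy(dtype=float)
    quintile = cohort["quintile"].to_numpy(dtype=int)
    X = design_matrix(entry, female, quintile)
    end_age = entry + horizon

    inc_scale = {d: np.exp(X @ draw.incidence[d].beta) for d in DISEASES}
    inc_gamma = {d: draw.incidence[d].gamma for d in DISEASES}

    mask = np.zeros(n, dtype=np.int64)
    age_now = entry.copy()
    death_age = np.full(n, np.nan)
    disease_age = {d: np.full(n, np.nan) for d in DISEASES}
    active = np.ones(n, dtype=bool)

    while active.any():
        idx = np.flatnonzero(active)
        t_cand = np.full((len(DISEASES) + 1, len(idx)), np.inf)
        # mortality depends on the current condition set
        for m in np.unique(mask[idx]):
            sub = idx[mask[idx] == m]
            params = composed_mortality_params(draw, mask_diseases(int(m)))
            scale = np.exp(X[sub] @ params.beta)
            t = _conditional_weibull_sample(rng, params.gamma, scale, age_now[sub])
            t_cand[-1, np.searchsorted(idx, sub)] = t
        for j, d in enumerate(DISEASES):
            free = (mask[idx] >> j & 1) == 0
            sub = idx[free]
            t = _conditional_weibull_sample(
                rng, inc_gamma[d], inc_scale[d][sub], age_now[sub]
            )
            t_cand[j, np.searchsorted(idx, sub)] = t

        winner = np.argmin(t_cand, axis=0)
        t_min = t_cand[winner, np.arange(len(idx))]
        censored = t_min >= end_age[idx]
        active[idx[censored]] = False
        hit = idx[~censored]
        w = winner[~censored]
        t_hit = t_min[~censored]
        died = w == len(DISEASES)
        death_age[hit[died]] = t_hit[died]
        active[hit[died]] = False
        for j, d in enumerate(DISEASES):
            got = hit[w == j]
            disease_age[d][got] = t_hit[w == j]
            mask[got] |= 1 << j
            age_now[got] = t_hit[w == j]

    stop_age = np.where(np.isnan(death_age), end_age, death_age)

    events = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "female": cohort["female"].to_numpy(),
            "quintile": cohort["quintile"].to_numpy(),
            "entry_age": entry,
            "end_age": stop_age,
        }
    )
    for d in DISEASES:
        got = ~np.isnan(disease_age[d])
        events[f"event_{d}"] = got.astype(np.int8)
        events[f"age_{d}"] = np.where(got, disease_age[d], stop_age)
    died = ~np.isnan(death_age)
    events["event_death"] = died.astype(np.int8)
    events["age_death"] = stop_age

    # ---- person-year table: depression indicator and annual costs ----------
    n_years = np.ceil(stop_age - entry - 1e-9).astype(int)
    n_years = np.maximum(n_years, 0)
    pid = np.repeat(np.arange(n), n_years)
    year = np.concatenate([np.arange(k) for k in n_years]) if len(pid) else np.empty(0, int)
    age_py = entry[pid] + year
    mask_py = np.zeros(len(pid), dtype=np.int64)
    for j, d in enumerate(DISEASES):
        acquired = ~np.isnan(disease_age[d][pid]) & (disease_age[d][pid] <= age_py + 1e-12)
        mask_py |= acquired.astype(np.int64) << j

    Xpy = design_matrix(age_py, female[pid], quintile[pid])
    logit = np.empty(len(pid))
    for m in np.unique(mask_py) if len(pid) else []:
        sel = mask_py == m
        logit[sel] = composed_depression_logit(draw, mask_diseases(int(m)), Xpy[sel])
    depressed = (rng.random(len(pid)) < expit(logit)).astype(np.int8) if len(pid) else np.empty(0, np.int8)

    Xc = design_matrix(age_py, female[pid], quintile[pid], depressed.astype(float))
    p_nz = np.empty(len(pid))
    mean_pos = np.empty(len(pid))
    for m in np.unique(mask_py) if len(pid) else []:
        sel = mask_py == m
        cp = composed_cost_params(draw, mask_diseases(int(m)))
        p_nz[sel] = norm.cdf(Xc[sel] @ cp.beta_probit)
        mean_pos[sel] = np.exp(Xc[sel] @ cp.beta_gamma)
    shape = draw_cost_shape(truth)
    nonzero = rng.random(len(pid)) < p_nz
    cost = np.zeros(len(pid))
    if nonzero.any():
        cost[nonzero] = rng.gamma(shape, mean_pos[nonzero] / shape)

    person_years = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy()[pid] if len(pid) else np.empty(0, np.int64),
            "year": year,
            "age": age_py,
            "female": female[pid].astype(np.int8) if len(pid) else np.empty(0, np.int8),
            "quintile": quintile[pid].astype(np.int8) if len(pid) else np.empty(0, np.int8),
            "mask": mask_py,
            "depressed": depressed,
            "cost": cost,
        }
    )
    return RegistryTable(events=events, person_years=person_years)


def draw_cost_shape(truth: InputModelSet | ParameterDraw) -> float:
    """Gamma dispersion used when simulating positive annual costs."""
    if isinstance(truth, InputModelSet):
        return float(truth.cost["AT_RISK"].gamma_shape)
    return 1.2


def generate_activity_survey(
    n: int, seed: int, truth_dist: ActivityDistribution
) -> pd.DataFrame:
    """Draw survey respondents and their activity category per stratum.

    Respondents are spread uniformly over sex, age band and quintile;
    the category is multinomial with the stratum's configured proportions.
    """
    if n < 0:
        raise ConfigurationError("n must be non-negative")
    rng = np.random.default_rng(seed)
    female = rng.integers(0, 2, size=n)
    band = rng.integers(0, len(AGE_BANDS), size=n)
    quintile = rng.integers(1, 6, size=n)
    category = np.empty(n, dtype=object)
    for f in (0, 1):
        for b in range(len(AGE_BANDS)):
            for q in range(1, 6):
                sel = (female == f) & (band == b) & (quintile == q)
                if not sel.any():
                    continue
                p = truth_dist.proportions(bool(f), b, q)
                category[sel] = rng.choice(
                    np.array(["inactive", "insufficient", "active"]), size=sel.sum(), p=p
                )
    return pd.DataFrame(
        {
            "female": female.astype(np.int8),
            "age_band": band.astype(np.int8),
            "quintile": quintile.astype(np.int8),
            "activity": category if n else np.empty(0, dtype=object),
        }
    )


def age_standardize(prevalence_by_band: np.ndarray, standard_weights: np.ndarray) -> float:
    """Directly age-standardised proportion: weighted mean over age bands."""
    p = np.asarray(prevalence_by_band, dtype=float)
    w = np.asarray(standard_weights, dtype=float)
    if p.shape != w.shape:
        raise ConfigurationError("prevalence and weight vectors must have the same length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigurationError("weights must be non-negative with a positive sum")
    return float((w * p).sum() / w.sum())
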