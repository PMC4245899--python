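"""Intervention effect as a potential impact fraction (PIF).

A brief primary-care intervention shifts the population physical-activity
distribution (three categories: inactive / insufficiently active / active)
by applying the trial odds ratio (default 1.42, 95% interval 1.17-1.73) to
the odds of being *active*.  Combining the baseline and shifted
distributions with per-disease relative risks for inactivity gives, per
stratum, the PIF

    PIF = (sum_i p_i RR_i - sum_i p'_i RR_i) / sum_i p_i RR_i

and the multiplier ``m = 1 - PIF`` applied to at-risk disease-incidence
transition probabilities for the duration of the effect (default 5 years).

The intervention cost is a fixed cost per person-year among the at-risk
population: one GP consultation (default £35) for the not-sufficiently
active, and a screening fraction of it (default 20%) for the active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .states import DISEASES

CATEGORIES = ("inactive", "insufficient", "active")

#: 10-year age bands used to stratify the activity distribution.
AGE_BANDS = ("16-25", "26-35", "36-45", "46-55", "56-65", "66-75", "76+")
_BAND_LOWER = np.array([16, 26, 36, 46, 56, 66, 76], dtype=float)


def band_for_age(age: np.ndarray | float) -> np.ndarray:
    """Index of the 10-year age band containing ``age`` (clipped to 16+)."""
    age = np.asarray(age, dtype=float)
    return np.clip(np.searchsorted(_BAND_LOWER, age, side="right") - 1, 0, len(AGE_BANDS) - 1)


@dataclass
class ActivityDistribution:
    """Three-category activity prevalences per sex x age-band x quintile.

    ``table`` columns: female (0/1), age_band (index), quintile (1-5),
    p_inactive, p_insufficient, p_active.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.table[["p_inactive", "p_insufficient", "p_active"]].to_numpy()
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ConfigurationError("activity proportions must lie in [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError("activity proportions must sum to 1 per stratum")

    def row(self, female: bool, band: int, quintile: int) -> pd.Series:
        t = self.table
        m = (t["female"] == int(female)) & (t["age_band"] == band) & (t["quintile"] == quintile)
        sel = t.loc[m]
        if len(sel) != 1:
            raise ConfigurationError(
                f"activity stratum (female={female}, band={band}, quintile={quintile}) "
                f"matched {len(sel)} rows"
            )
        return sel.iloc[0]

    def proportions(self, female: bool, band: int, quintile: int) -> np.ndarray:
        r = self.row(female, band, quintile)
        return np.array([r["p_inactive"], r["p_insufficient"], r["p_active"]])

    def p_active_by_band(self, female: bool, quintile: int) -> np.ndarray:
        t = self.table
        m = (t["female"] == int(female)) & (t["quintile"] == quintile)
        sel = t.loc[m].sort_values("age_band")
        return sel["p_active"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class RelativeRiskSet:
    """Per-disease relative risks for inactive / insufficient vs active (=1)."""

    rr: dict[str, tuple[float, float]]  # disease -> (RR_inactive, RR_insufficient)

    def __post_init__(self) -> None:
        for d, (ri, rs) in self.rr.items():
            if d not in DISEASES:
                raise ConfigurationError(f"unknown disease '{d}' in relative-risk set")
            if ri <= 0 or rs <= 0:
                raise ConfigurationError("relative risks must be positive")

    def vector(self, disease: str) -> np.ndarray:
        ri, rs = self.rr[disease]
        return np.array([ri, rs, 1.0])


@dataclass
class InterventionSpec:
    """Trial effect, duration, cost schedule and per-quintile variations."""

    or_active: float = 1.42
    or_interval: tuple[float, float] = (1.17, 1.73)  # 95% interval of the OR
    duration: int = 5  # years the effect (and cost) is maintained
    unit_cost: float = 35.0  # GBP per person-year, not sufficiently active
    screening_fraction: float = 0.2  # fraction of unit cost for the active
    attenuation: np.ndarray = field(default_factory=lambda: np.zeros(5))  # per quintile
    cost_multiplier: np.ndarray = field(default_factory=lambda: np.ones(5))  # per quintile

    def __post_init__(self) -> None:
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        self.cost_multiplier = np.asarray(self.cost_multiplier, dtype=float)
        if self.or_active <= 0:
            raise ConfigurationError("or_active must be positive")
        if self.duration < 0 or self.unit_cost < 0 or self.screening_fraction < 0:
            raise ConfigurationError("duration and costs must be non-negative")
        if np.any(self.attenuation < 0) or np.any(self.attenuation > 1):
            raise ConfigurationError("attenuation fractions must lie in [0, 1]")

    def or_log_sd(self) -> float:
        lo, hi = self.or_interval
        return (np.log(hi) - np.log(lo)) / (2.0 * 1.959963984540054)

    def sample_or(self, rng: np.random.Generator) -> float:
        """Lognormal OR draw centred on log(or_active) for the PSA."""
        return float(np.exp(np.log(self.or_active) + self.or_log_sd() * rng.standard_normal()))


def shift_activity_distribution(
    dist: ActivityDistribution, or_active: float
) -> ActivityDistribution:
    """Apply the trial odds ratio to the odds of being active, per stratum.

    The gain in the active proportion is removed from the inactive and
    insufficient categories in proportion to their sizes.  Strata with
    p_active in {0, 1} are returned unchanged (zero or infinite odds).
    """
    if or_active <= 0:
        raise ConfigurationError("or_active must be positive")
    t = dist.table.copy()
    pa = t["p_active"].to_numpy(dtype=float)
    pin = t["p_inactive"].to_numpy(dtype=float)
    pins = t["p_insufficient"].to_numpy(dtype=float)

    movable = (pa > 0.0) & (pa < 1.0)
    odds = np.where(movable, pa / np.where(pa < 1.0, 1.0 - pa, 1.0), 0.0)
    pa_new = np.where(movable, or_active * odds / (1.0 + or_active * odds), pa)
    gain = pa_new - pa
    non_active = pin + pins
    frac_in = np.where(non_active > 0, pin / np.where(non_active > 0, non_active, 1.0), 0.0)
    t["p_inactive"] = pin - gain * frac_in
    t["p_insufficient"] = pins - gain * (1.0 - frac_in)
    t["p_active"] = pa_new
    return ActivityDistribution(t)


def potential_impact_fraction(
    p: np.ndarray, p_shifted: np.ndarray, rr: RelativeRiskSet, disease: str
) -> float:
    """PIF over the three activity categories for one disease and stratum."""
    r = rr.vector(disease)
    p = np.asarray(p, dtype=float)
    p_shifted = np.asarray(p_shifted, dtype=float)
    denom = float(p @ r)
    if denom == 0.0:
        raise ConfigurationError("sum of p_i * RR_i is zero; PIF undefined")
    return (denom - float(p_shifted @ r)) / denom


def incidence_multiplier(pif: float) -> float:
    """Multiplier ``m = 1 - PIF`` on at-risk incidence transition probabilities."""
    return 1.0 - pif


def attenuate_multiplier(m: float, attenuation: float) -> float:
    """Attenuate the intervention effect: ``m' = 1 - (1 - a) * (1 - m)``."""
    return 1.0 - (1.0 - attenuation) * (1.0 - m)


def pif_table(
    dist: ActivityDistribution, or_active: float, rr: RelativeRiskSet
) -> pd.DataFrame:
    """PIF and incidence multiplier per stratum and disease.

    Tidy frame with columns female, age_band, quintile, disease, pif,
    multiplier; exportable to CSV.
    """
    shifted = shift_activity_distribution(dist, or_active)
    rows = []
    for (idx, base), (_, shift) in zip(dist.table.iterrows(), shifted.table.iterrows()):
        p = base[["p_inactive", "p_insufficient", "p_active"]].to_numpy(dtype=float)
        q = shift[["p_inactive", "p_insufficient", "p_active"]].to_numpy(dtype=float)
        for d in DISEASES:
            pif = potential_impact_fraction(p, q, rr, d)
            rows.append(
                {
                    "female": int(base["female"]),
                    "age_band": int(base["age_band"]),
                    "quintile": int(base["quintile"]),
                    "disease": d,
                    "pif": pif,
                    "multiplier": incidence_multiplier(pif),
                }
            )
    return pd.DataFrame(rows)


def multiplier_lookup(
    dist: ActivityDistribution,
    or_active: float,
    rr: RelativeRiskSet,
    female: bool,
    quintile: int,
    attenuation: float = 0.0,
) -> np.ndarray:
    """Attenuated incidence multipliers, shape (n_age_bands, n_diseases).

    Band b, disease d holds the multiplier applied to the at-risk incidence
    of disease d for cohort members whose current age falls in band b.
    """
    shifted = shift_activity_distribution(dist, or_active)
    out = np.ones((len(AGE_BANDS), len(DISEASES)))
    for b in range(len(AGE_BANDS)):
        p = dist.proportions(female, b, quintile)
        q = shifted.proportions(female, b, quintile)
        for j, d in enumerate(DISEASES):
            m = incidence_multiplier(potential_impact_fraction(p, q, rr, d))
            out[b, j] = attenuate_multiplier(m, attenuation)
    return out


def intervention_cost_per_person_year(
    p_active: float, spec: InterventionSpec, cycle: int, quintile: int
) -> float:
    """Cost per at-risk person-year in a given cycle (1-based) and quintile.

    Zero once the effect (and delivery) period is over; otherwise the
    not-sufficiently-active pay the unit cost and the active the screening
    fraction of it, scaled by the quintile cost multiplier.
    """
    if cycle < 1:
        raise ConfigurationError("cycle index is 1-based")
    if cycle > spec.duration:
        return 0.0
    cm = float(spec.cost_multiplier[quintile - 1])
    return cm * (
        (1.0 - p_active) * spec.unit_cost + p_active * spec.screening_fraction * spec.unit_cost
    )
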