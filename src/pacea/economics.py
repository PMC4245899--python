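"""Economic evaluation: QALYs, costs, increments, NHB, CEAC and the PSA.

Person-year flows from the Markov engine are weighted by state utilities
(multiplicative combination of single-condition utilities relative to the
healthy baseline, with a depression multiplier) and by predicted mean
annual health-care costs, then discounted.  Half-cycle-corrected flows are
mid-cycle quantities, so cycle ``t`` discounts by ``(1+r)**(t-0.5)``.

Incremental results compare intervention and standard care under the same
parameter draw (common random parameters, so increments isolate the
intervention effect).  Net health benefit at willingness-to-pay ``lambda``
is ``NHB = dE - dC/lambda``; the cost-effectiveness acceptability curve is
the fraction of simulations with positive net benefit across thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PaceaError
from .estimation import InputModelSet, ParameterDraw, sample_parameter_draw
from .intervention import (
    ActivityDistribution,
    InterventionSpec,
    RelativeRiskSet,
    band_for_age,
    intervention_cost_per_person_year,
    multiplier_lookup,
)
from .markov import (
    AGE_CAP,
    assemble_matrix_stack,
    compute_transition_tables,
    life_years_summary,
    run_cohort_batch,
)
from .registry import Demographics
from .states import StateSpace, build_state_space, mask_diseases

logger = logging.getLogger(__name__)


@dataclass
class UtilityTable:
    """State utilities: healthy baseline, per-condition values, depression
    multiplier; combination is multiplicative relative to the baseline."""

    at_risk: float
    disease: dict[str, float]
    depression_multiplier: float
    rule: str = "multiplicative"

    def __post_init__(self) -> None:
        if not 0.0 < self.at_risk <= 1.0:
            raise ConfigurationError("at-risk utility must lie in (0, 1]")
        for d, u in self.disease.items():
            if u > self.at_risk:
                raise ConfigurationError(f"utility of {d} exceeds the at-risk utility")
            if u <= 0:
                raise ConfigurationError(f"utility of {d} must be positive")
        if not 0.0 < self.depression_multiplier <= 1.0:
            raise ConfigurationError("depression multiplier must lie in (0, 1]")


def state_utility(mask: int, depressed: bool, table: UtilityTable) -> float:
    """Utility of an alive state; DEAD (mask < 0) has utility 0."""
    if mask < 0:
        return 0.0
    u = table.at_risk
    for d in mask_diseases(mask):
        u *= table.disease[d] / table.at_risk
    if depressed:
        u *= table.depression_multiplier
    return u


def utility_vector(table: UtilityTable, space: StateSpace | None = None) -> np.ndarray:
    space = space or build_state_space()
    return np.array(
        [
            state_utility(int(space.masks[s]), bool(space.depressed[s]), table)
            if s != space.dead_index
            else 0.0
            for s in range(space.n_states)
        ]
    )


@dataclass
class EconParams:
    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    discount_rate_qalys_alt: float = 0.015  # sensitivity analysis
    wtp_threshold: float = 30_000.0  # GBP per QALY
    n_sims: int = 2000
    per_entrants: float = 1000.0  # results per 1000 entering the model
    ceac_thresholds: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 50_001.0, 1000.0)
    )

    def __post_init__(self) -> None:
        if min(self.discount_rate_costs, self.discount_rate_qalys, self.discount_rate_qalys_alt) < 0:
            raise ConfigurationError("discount rates must be non-negative")
        if self.wtp_threshold <= 0:
            raise ConfigurationError("willingness-to-pay threshold must be positive")
        if self.n_sims < 1:
            raise ConfigurationError("n_sims must be at least 1")


def discounted_sum(values_by_cycle: np.ndarray, rate: float, half_cycle: bool = True) -> float:
    """Discount per-cycle values (cycle 1 first); mid-cycle timing when
    ``half_cycle`` (appropriate for half-cycle-corrected flows)."""
    v = np.asarray(values_by_cycle, dtype=float)
    t = np.arange(1, len(v) + 1, dtype=float)
    if half_cycle:
        t = t - 0.5
    return float(np.sum(v / (1.0 + rate) ** t))


def accumulate_qalys(person_years: np.ndarray, table: UtilityTable, rate: float,
                     space: StateSpace | None = None) -> float:
    """Discounted QALYs from a (n_cycles, 33) person-year array."""
    u = utility_vector(table, space)
    flow = np.asarray(person_years, dtype=float) @ u
    return discounted_sum(flow, rate, half_cycle=True)


# ---------------------------------------------------------------------------
# Single-arm run
# ---------------------------------------------------------------------------


@dataclass
class ArmResult:
    """Per-cycle flows (cycle 1 first) and life-year aggregates for one
    arm / sex / quintile run, scaled to the configured entrant count."""

    qaly_flow: np.ndarray  # utility-weighted person-years per cycle
    health_cost_flow: np.ndarray  # non-intervention health-care cost per cycle
    intervention_cost_flow: np.ndarray  # intervention delivery cost per cycle
    life_years: dict[str, float]  # undiscounted aggregates per 1000


def _prepare_run(draw, female, quintile, demographics, space):
    """Shared preparation for both arms: age grid, tables, control matrices
    and the initial at-risk occupancy over integer entry ages."""
    ages = np.arange(int(demographics.age_min), AGE_CAP)
    tables = compute_transition_tables(draw, female, quintile, ages, space)
    M_control = assemble_matrix_stack(tables, space)
    entry_ages, weights = demographics.integer_age_weights(female, quintile)
    entrants = 1000.0
    initial = np.zeros((len(entry_ages), space.n_states))
    i_no, i_dep = space.alive_indices(0)
    pi0 = tables.dep_prev[tables.age_index(entry_ages), 0]
    initial[:, i_no] = entrants * weights * (1.0 - pi0)
    initial[:, i_dep] = entrants * weights * pi0
    return ages, tables, M_control, entry_ages, initial, entrants


def _flows_from_occupancy(occ, tables, ages, entry_ages, entrants, arm, spec, dist,
                          quintile, female, utilities, space, n_cycles):
    """Turn an occupancy trace into per-cycle QALY and cost flows."""
    py = 0.5 * (occ[:-1, :, : space.n_states] + occ[1:, :, : space.n_states])  # (T, e, s)
    u = utility_vector(utilities, space)
    qaly_flow = np.einsum("tes,s->t", py, u)

    # non-intervention health-care costs: state- and age-specific means
    T = n_cycles
    cost_flow = np.zeros(T)
    age_idx_cap = len(ages) - 1
    for t in range(T):
        idx = np.clip(entry_ages + t - int(ages[0]), 0, age_idx_cap)
        cost_flow[t] = np.einsum("es,es->", py[t], tables.mean_cost[idx])

    ivc_flow = np.zeros(T)
    if arm == "intervention":
        ar_states = list(space.alive_indices(0))
        for t in range(1, min(spec.duration, T) + 1):
            age_t = np.minimum(entry_ages + t - 1, AGE_CAP - 1)
            bands = band_for_age(age_t)
            py_ar = py[t - 1][:, ar_states].sum(axis=1)
            for b in np.unique(bands):
                p_act = float(dist.row(female, int(b), quintile)["p_active"])
                cpy = intervention_cost_per_person_year(p_act, spec, t, quintile)
                ivc_flow[t - 1] += py_ar[bands == b].sum() * cpy

    ly = life_years_summary(py.sum(axis=1), entrants, space)
    return ArmResult(qaly_flow=qaly_flow, health_cost_flow=cost_flow,
                     intervention_cost_flow=ivc_flow, life_years=ly)


def run_arm_pair(
    draw: ParameterDraw,
    female: bool,
    quintile: int,
    spec: InterventionSpec,
    dist: ActivityDistribution,
    rr: RelativeRiskSet,
    utilities: UtilityTable,
    demographics: Demographics,
    or_active: float | None = None,
    n_cycles: int = 70,
    space: StateSpace | None = None,
) -> dict[str, ArmResult]:
    """Run intervention and control under one shared parameter draw."""
    space = space or build_state_space()
    ages, tables, M_control, entry_ages, initial, entrants = _prepare_run(
        draw, female, quintile, demographics, space
    )
    lookup = multiplier_lookup(
        dist,
        or_active if or_active is not None else spec.or_active,
        rr,
        female,
        quintile,
        attenuation=float(spec.attenuation[quintile - 1]),
    )
    M_effect = assemble_matrix_stack(
        tables, space, incidence_multipliers=lookup[band_for_age(ages)]
    )
    occ_i = run_cohort_batch(
        initial, entry_ages, M_effect, ages, n_cycles, AGE_CAP, space,
        matrices_after=M_control, switch_after=spec.duration,
    )
    occ_c = run_cohort_batch(initial, entry_ages, M_control, ages, n_cycles, AGE_CAP, space)
    out = {}
    for arm, occ in (("intervention", occ_i), ("control", occ_c)):
        out[arm] = _flows_from_occupancy(
            occ, tables, ages, entry_ages, entrants, arm, spec, dist,
            quintile, female, utilities, space, n_cycles,
        )
    return out


def run_arm(
    draw: ParameterDraw,
    female: bool,
    quintile: int,
    arm: str,
    spec: InterventionSpec,
    dist: ActivityDistribution,
    rr: RelativeRiskSet,
    utilities: UtilityTable,
    demographics: Demographics,
    or_active: float | None = None,
    n_cycles: int = 70,
    space: StateSpace | None = None,
) -> ArmResult:
    """Run one cohort arm (``"intervention"`` or ``"control"``).

    The cohort enters entirely at risk (split between the depressed and
    not-depressed halves by the predicted prevalence at entry age), spread
    over integer entry ages by the demographic age distribution, scaled to
    1000 entrants.
    """
    if arm not in ("intervention", "control"):
        raise ConfigurationError(f"unknown arm '{arm}'")
    space = space or build_state_space()
    if arm == "intervention":
        return run_arm_pair(draw, female, quintile, spec, dist, rr, utilities,
                            demographics, or_active, n_cycles, space)["intervention"]
    ages, tables, M_control, entry_ages, initial, entrants = _prepare_run(
        draw, female, quintile, demographics, space
    )
    occ = run_cohort_batch(initial, entry_ages, M_control, ages, n_cycles, AGE_CAP, space)
    return _flows_from_occupancy(occ, tables, ages, entry_ages, entrants, arm, spec,
                                 dist, quintile, female, utilities, space, n_cycles)


def pool_sexes(results: dict[bool, ArmResult], female_share: float) -> ArmResult:
    """Weight per-1000 per-sex results by the sex shares of entrants."""
    w = {True: female_share, False: 1.0 - female_share}
    qaly = sum(w[f] * r.qaly_flow for f, r in results.items())
    hc = sum(w[f] * r.health_cost_flow for f, r in results.items())
    ivc = sum(w[f] * r.intervention_cost_flow for f, r in results.items())
    keys = next(iter(results.values())).life_years.keys()
    ly = {k: sum(w[f] * r.life_years[k] for f, r in results.items()) for k in keys}
    return ArmResult(qaly, hc, ivc, ly)


# ---------------------------------------------------------------------------
# Increments, NHB, CEAC
# ---------------------------------------------------------------------------


@dataclass
class Increment:
    """Incremental (intervention minus control) results per 1000 entrants."""

    d_qalys: float  # discounted at the primary QALY rate
    d_qalys_alt: float  # discounted at the sensitivity rate
    d_cost_total: float
    d_cost_intervention: float
    d_cost_health: float
    d_life_years: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        resid = self.d_cost_total - (self.d_cost_intervention + self.d_cost_health)
        if abs(resid) > 1e-6 * max(1.0, abs(self.d_cost_total)):
            raise ConfigurationError("cost components do not sum to the total increment")

    @classmethod
    def from_components(cls, d_qalys, d_qalys_alt, d_cost_intervention, d_cost_health,
                        d_life_years=None):
        return cls(
            d_qalys=d_qalys,
            d_qalys_alt=d_qalys_alt,
            d_cost_total=d_cost_intervention + d_cost_health,
            d_cost_intervention=d_cost_intervention,
            d_cost_health=d_cost_health,
            d_life_years=d_life_years or {},
        )


def incremental_results(
    intervention_run: ArmResult, control_run: ArmResult, params: EconParams
) -> Increment:
    """Discount both arms' flows and difference them (same parameter draw)."""
    rq, rq_alt, rc = (
        params.discount_rate_qalys,
        params.discount_rate_qalys_alt,
        params.discount_rate_costs,
    )
    d_qalys = discounted_sum(intervention_run.qaly_flow, rq) - discounted_sum(
        control_run.qaly_flow, rq
    )
    d_qalys_alt = discounted_sum(intervention_run.qaly_flow, rq_alt) - discounted_sum(
        control_run.qaly_flow, rq_alt
    )
    d_ivc = discounted_sum(intervention_run.intervention_cost_flow, rc) - discounted_sum(
        control_run.intervention_cost_flow, rc
    )
    d_hc = discounted_sum(intervention_run.health_cost_flow, rc) - discounted_sum(
        control_run.health_cost_flow, rc
    )
    d_ly = {
        k: intervention_run.life_years[k] - control_run.life_years[k]
        for k in intervention_run.life_years
    }
    return Increment.from_components(d_qalys, d_qalys_alt, d_ivc, d_hc, d_ly)


def net_health_benefit(d_qalys: float, d_cost: float, wtp: float) -> float:
    """``NHB = dE - dC / lambda`` in QALYs (per 1000 entrants)."""
    if wtp <= 0:
        raise ConfigurationError("willingness-to-pay threshold must be positive")
    return d_qalys - d_cost / wtp


def ceac(d_qalys: np.ndarray, d_costs: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Probability cost-effective at each threshold: P(dE*lambda - dC > 0)."""
    dE = np.asarray(d_qalys, dtype=float)[:, None]
    dC = np.asarray(d_costs, dtype=float)[:, None]
    lam = np.asarray(thresholds, dtype=float)[None, :]
    return (dE * lam - dC > 0).mean(axis=0)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_LY_KEYS = ("disease_free", "single", "dual", "triple", "quadruple", "depressed")


@dataclass
class PsaResults:
    """Per-simulation increments and their summaries for one quintile."""

    quintile: int
    draws: pd.DataFrame  # one row per simulation
    ceac_curve: pd.DataFrame  # threshold, probability
    n_redraws: int
    seed: int
    params: EconParams

    def summary(self) -> pd.DataFrame:
        """Mean and equal-tailed 2.5-97.5 percentile interval per quantity."""
        rows = []
        for col in self.draws.columns:
            if col == "sim":
                continue
            v = self.draws[col].to_numpy()
            rows.append(
                {
                    "quantity": col,
                    "mean": float(np.mean(v)),
                    "lo2.5": float(np.percentile(v, 2.5)),
                    "hi97.5": float(np.percentile(v, 97.5)),
                }
            )
        return pd.DataFrame(rows)

    def probability_cost_effective(self, wtp: float | None = None) -> float:
        wtp = self.params.wtp_threshold if wtp is None else wtp
        nhb = net_health_benefit(
            self.draws["d_qalys"].to_numpy(), self.draws["d_cost_total"].to_numpy(), wtp
        )
        return float((nhb > 0).mean())


def run_psa(
    models: InputModelSet,
    spec: InterventionSpec,
    params: EconParams,
    quintile: int,
    seed: int,
    demographics: Demographics,
    dist: ActivityDistribution,
    rr: RelativeRiskSet,
    utilities: UtilityTable,
    n_cycles: int = 70,
    max_redraws: int = 10,
) -> PsaResults:
    """Run the PSA for one deprivation quintile.

    Each simulation draws one joint parameter set (shared between arms and
    sexes) and one trial odds ratio, runs intervention and control for each
    sex, pools by entrant sex shares and records the increments.  Failed
    draws are logged and re-drawn, never silently dropped.
    """
    space = build_state_space()
    female_share = float(demographics.female_share[quintile - 1])
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(params.n_sims + max_redraws)
    records = []
    n_redraws = 0
    next_spare = params.n_sims
    for i in range(params.n_sims):
        seq = child_seeds[i]
        for _attempt in range(max_redraws + 1):
            try:
                rng = np.random.default_rng(seq)
                draw = sample_parameter_draw(models, rng, sim_index=i)
                or_i = spec.sample_or(rng)
                per_sex = {
                    f: run_arm_pair(
                        draw, f, quintile, spec, dist, rr, utilities,
                        demographics, or_active=or_i, n_cycles=n_cycles, space=space,
                    )
                    for f in (False, True)
                }
                pooled = {
                    arm: pool_sexes({f: per_sex[f][arm] for f in per_sex}, female_share)
                    for arm in ("intervention", "control")
                }
                inc = incremental_results(pooled["intervention"], pooled["control"], params)
                if not np.all(np.isfinite([inc.d_qalys, inc.d_qalys_alt, inc.d_cost_total])):
                    raise PaceaError("non-finite increments under sampled parameters")
                break
            except (PaceaError, np.linalg.LinAlgError) as exc:
                n_redraws += 1
                if next_spare >= len(child_seeds):
                    raise
                logger.warning("simulation %d failed (%s); re-drawing", i, exc)
                seq = child_seeds[next_spare]
                next_spare += 1
        rec = {
            "sim": i,
            "d_qalys": inc.d_qalys,
            "d_qalys_alt": inc.d_qalys_alt,
            "d_cost_total": inc.d_cost_total,
            "d_cost_intervention": inc.d_cost_intervention,
            "d_cost_health": inc.d_cost_health,
            "nhb": net_health_benefit(inc.d_qalys, inc.d_cost_total, params.wtp_threshold),
            "or_active": or_i,
        }
        for k in _LY_KEYS:
            rec[f"d_ly_{k}"] = inc.d_life_years.get(k, np.nan)
        records.append(rec)

    draws = pd.DataFrame(records)
    curve = pd.DataFrame(
        {
            "threshold": params.ceac_thresholds,
            "probability": ceac(
                draws["d_qalys"].to_numpy(),
                draws["d_cost_total"].to_numpy(),
                params.ceac_thresholds,
            ),
        }
    )
    return PsaResults(
        quintile=quintile, draws=draws, ceac_curve=curve,
        n_redraws=n_redraws, seed=seed, params=params,
    )
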