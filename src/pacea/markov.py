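"""Cohort Markov engine.

Per parameter draw, sex and deprivation quintile the engine tabulates, for
every attained age, the annual probabilities of death (per condition
subset), of disease incidence (from the at-risk state), the depression
prevalence (per condition subset) and the mean annual cost (per state).
From these it assembles row-stochastic 33x33 transition matrices and steps
a closed cohort over annual cycles.

Within-cycle structure: death competes first (state-specific mortality);
survivors may acquire at most one new condition in the year (per-condition
probabilities; proportional rescaling guards the pathological case where
they would sum beyond 1); depression is reassigned in every alive
destination from the state-specific prevalence (memoryless).  Chronic
conditions are irreversible; DEAD is absorbing.  Members reaching age 100
leave the model through an EXITED accounting bucket after completing the
cycle and accrue no further person-years, costs or QALYs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .estimation import (
    ParameterDraw,
    annual_transition_probability,
    composed_cost_params,
    composed_depression_logit,
    composed_mortality_params,
    design_matrix,
)
from .states import DISEASES, N_MASKS, StateSpace, build_state_space, mask_diseases
from scipy.special import expit
from scipy.stats import norm

AGE_CAP = 100  # exit age ("died or reached 100 years of age")

#: Column index, beyond the 33 states, of the age-100 exit bucket in traces.
EXITED_COL = 33


@dataclass
class TransitionTables:
    """Age-indexed annual probabilities and predictions for one draw/sex/quintile."""

    ages: np.ndarray  # year-start attained ages covered by the tables
    p_death: np.ndarray  # (n_ages, 16) per condition subset
    p_inc: np.ndarray  # (n_ages, 4) at-risk incidence, per condition
    dep_prev: np.ndarray  # (n_ages, 16) depression prevalence per subset
    mean_cost: np.ndarray  # (n_ages, 33) mean annual cost per state

    def age_index(self, age: np.ndarray | int) -> np.ndarray:
        return np.asarray(age, dtype=int) - int(self.ages[0])


def compute_transition_tables(
    draw: ParameterDraw,
    female: bool,
    quintile: int,
    ages: np.ndarray,
    space: StateSpace | None = None,
) -> TransitionTables:
    """Evaluate all input models on an attained-age grid.

    Covariates use the cycle-updated age (entry age + cycle), the sex and
    quintile of the run.
    """
    space = space or build_state_space()
    ages = np.asarray(ages, dtype=float)
    X = design_matrix(ages, float(female), quintile)
    n_ages = len(ages)

    p_inc = np.column_stack(
        [annual_transition_probability(draw.incidence[d], X, ages) for d in DISEASES]
    )
    p_death = np.empty((n_ages, N_MASKS))
    dep_prev = np.empty((n_ages, N_MASKS))
    for m in range(N_MASKS):
        diseases = mask_diseases(m)
        p_death[:, m] = annual_transition_probability(
            composed_mortality_params(draw, diseases), X, ages
        )
        dep_prev[:, m] = expit(composed_depression_logit(draw, diseases, X))

    mean_cost = np.zeros((n_ages, space.n_states))
    for s in range(space.n_states - 1):  # DEAD costs nothing
        m = int(space.masks[s])
        cp = composed_cost_params(draw, mask_diseases(m))
        Xc = design_matrix(ages, float(female), quintile, float(space.depressed[s]))
        mean_cost[:, s] = norm.cdf(Xc @ cp.beta_probit) * np.exp(Xc @ cp.beta_gamma)
    return TransitionTables(ages=ages, p_death=p_death, p_inc=p_inc, dep_prev=dep_prev, mean_cost=mean_cost)


def assemble_matrix_stack(
    tables: TransitionTables,
    space: StateSpace | None = None,
    incidence_multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """Row-stochastic transition matrices for every tabulated age.

    ``incidence_multipliers`` — optional (n_ages, 4) array of intervention
    multipliers applied to the at-risk incidence probabilities (the
    intervention only modifies incidence in healthy at-risk members).
    Returns an array of shape (n_ages, 33, 33).
    """
    space = space or build_state_space()
    n_ages = len(tables.ages)
    n = space.n_states
    dead = space.dead_index
    M = np.zeros((n_ages, n, n))

    for m in range(N_MASKS):
        pd_ = tables.p_death[:, m]
        free = [j for j in range(len(DISEASES)) if not m >> j & 1]
        q = tables.p_inc[:, free].copy() if free else np.zeros((n_ages, 0))
        if m == 0 and incidence_multipliers is not None:
            q *= incidence_multipliers
        total = q.sum(axis=1)
        over = total > 1.0
        if np.any(over):  # guard: proportional rescale, never hit at realistic inputs
            q[over] *= (1.0 / total[over])[:, None]
            total = np.minimum(total, 1.0)
        survive = 1.0 - pd_

        row = np.zeros((n_ages, n))
        row[:, dead] = pd_

        def deposit(dest_mask: int, share: np.ndarray) -> None:
            pi = tables.dep_prev[:, dest_mask]
            i_no, i_dep = space.alive_indices(dest_mask)
            row[:, i_no] += share * (1.0 - pi)
            row[:, i_dep] += share * pi

        deposit(m, survive * (1.0 - total))
        for k, j in enumerate(free):
            deposit(m | (1 << j), survive * q[:, k])

        if np.any(row < -1e-12) or np.any(row > 1.0 + 1e-12) or not np.all(np.isfinite(row)):
            bad = np.argwhere((row < -1e-12) | (row > 1 + 1e-12) | ~np.isfinite(row))[0]
            raise ValidationError(
                f"transition probability out of [0,1] at age index {bad[0]}, "
                f"destination '{space.names[bad[1]]}'"
            )
        for src in space.alive_indices(m):  # identical for dep / nodep sources
            M[:, src, :] = row
    M[:, dead, dead] = 1.0
    return M


@dataclass
class CohortTrace:
    """Occupancy per state per cycle for one single-entry-age cohort run.

    ``occupancy`` has shape (n_cycles+1, 34): the 33 states plus the EXITED
    bucket for members who completed the cycle in which they reached the age
    cap.  Row sums are conserved at the starting count.
    """

    occupancy: np.ndarray
    entry_age: int
    meta: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def starting_count(self) -> float:
        return float(self.occupancy[0].sum())


def run_cohort(
    initial: np.ndarray,
    matrices: np.ndarray,
    ages: np.ndarray,
    entry_age: int,
    n_cycles: int = 70,
    age_cap: int = AGE_CAP,
    space: StateSpace | None = None,
    meta: dict | None = None,
) -> CohortTrace:
    """Step a cohort starting at ``entry_age`` through ``n_cycles`` annual cycles.

    ``matrices`` is the age-indexed stack from :func:`assemble_matrix_stack`
    covering at least ages ``entry_age .. min(entry_age+n_cycles, age_cap)-1``.
    Works for any square stack whose last state is absorbing death (reduced
    toy models included); ``space`` only sets the expected dimension.
    """
    matrices = np.asarray(matrices, dtype=float)
    n = matrices.shape[1]
    dead = n - 1
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (n,):
        raise ValidationError(f"initial occupancy must have length {n}")
    a0 = int(ages[0])
    occ = np.zeros((n_cycles + 1, n + 1))
    occ[0, :n] = initial
    current = initial.copy()
    exited = 0.0
    for t in range(1, n_cycles + 1):
        age = entry_age + t - 1  # age during cycle t
        if age < age_cap:
            current = current @ matrices[min(age - a0, len(matrices) - 1)]
        if entry_age + t >= age_cap:
            alive = current.copy()
            alive[dead] = 0.0
            exited += alive.sum()
            current[:dead] = 0.0
        occ[t, :n] = current
        occ[t, n] = exited
    return CohortTrace(occupancy=occ, entry_age=entry_age, meta=meta or {})


def run_cohort_batch(
    initial: np.ndarray,
    entry_ages: np.ndarray,
    matrices: np.ndarray,
    ages: np.ndarray,
    n_cycles: int = 70,
    age_cap: int = AGE_CAP,
    space: StateSpace | None = None,
    matrices_after: np.ndarray | None = None,
    switch_after: int | None = None,
) -> np.ndarray:
    """Step many single-entry-age cohorts simultaneously.

    ``initial`` has shape (n_entry, 33); returns occupancy of shape
    (n_cycles+1, n_entry, 34) with the EXITED bucket in the last column.
    When ``matrices_after``/``switch_after`` are given, cycles beyond
    ``switch_after`` use the alternative stack (intervention effect ending).
    """
    space = space or build_state_space()
    n = space.n_states
    entry_ages = np.asarray(entry_ages, dtype=int)
    a0 = int(ages[0])
    n_entry = len(entry_ages)
    occ = np.zeros((n_cycles + 1, n_entry, n + 1))
    occ[0, :, :n] = initial
    current = np.asarray(initial, dtype=float).copy()
    exited = np.zeros(n_entry)
    for t in range(1, n_cycles + 1):
        M = matrices if switch_after is None or t <= switch_after else matrices_after
        age = entry_ages + t - 1
        live = age < age_cap
        if live.any():
            idx = np.clip(age - a0, 0, len(M) - 1)
            stepped = np.einsum("es,esj->ej", current[live], M[idx[live]])
            current[live] = stepped
        capped = entry_ages + t >= age_cap
        if capped.any():
            alive_mass = current[capped].sum(axis=1) - current[capped, space.dead_index]
            exited[capped] += alive_mass
            current[capped, : space.dead_index] = 0.0
        occ[t, :, :n] = current
        occ[t, :, n] = exited
    return occ


def half_cycle_corrected_person_years(
    occupancy: np.ndarray, n_states: int = 33
) -> np.ndarray:
    """Trapezoid person-years per state per cycle.

    ``occupancy`` is a (n_cycles+1, >=n_states) trace; cycle ``t``
    person-years are the mean of adjacent occupancies, returned as shape
    (n_cycles, n_states).  The EXITED accounting column accrues nothing.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.ndim != 2 or occupancy.shape[0] < 2:
        raise ValidationError("trace must contain at least two cycles of occupancy")
    states = occupancy[:, :n_states]
    return 0.5 * (states[:-1] + states[1:])


def life_years_summary(
    person_years: np.ndarray, entrants: float, space: StateSpace | None = None
) -> dict[str, float]:
    """Aggregate (undiscounted) life-years per 1000 entrants by category."""
    space = space or build_state_space()
    py = np.asarray(person_years, dtype=float)
    totals = py.sum(axis=0)  # per state
    scale = 1000.0 / entrants
    n_cond = np.array(
        [bin(int(m)).count("1") if m >= 0 else -1 for m in space.masks]
    )
    alive = np.arange(space.n_states) != space.dead_index
    out = {
        "total": float(totals[alive].sum()) * scale,
        "disease_free": float(totals[(n_cond == 0) & alive].sum()) * scale,
        "single": float(totals[n_cond == 1].sum()) * scale,
        "dual": float(totals[n_cond == 2].sum()) * scale,
        "triple": float(totals[n_cond == 3].sum()) * scale,
        "quadruple": float(totals[n_cond == 4].sum()) * scale,
        "depressed": float(totals[space.depressed & alive].sum()) * scale,
    }
    return out


def microsimulate(
    initial_counts: np.ndarray,
    matrices: np.ndarray,
    ages: np.ndarray,
    entry_age: int,
    n_cycles: int,
    rng: np.random.Generator,
    age_cap: int = AGE_CAP,
) -> np.ndarray:
    """Individual-level stochastic replica of :func:`run_cohort`.

    Steps each of the ``initial_counts.sum()`` individuals through the same
    per-cycle matrices by sampling the destination state, and returns the
    integer occupancy trace (n_cycles+1, n_states+1).  Used as an
    independent Monte-Carlo oracle for the cohort recursion in tests.
    """
    n = matrices.shape[1]
    a0 = int(ages[0])
    counts = np.asarray(initial_counts, dtype=int)
    state = np.repeat(np.arange(n), counts)
    rng.shuffle(state)
    exited = np.zeros(len(state), dtype=bool)
    trace = np.zeros((n_cycles + 1, n + 1))
    trace[0, :n] = np.bincount(state, minlength=n)
    dead = n - 1
    for t in range(1, n_cycles + 1):
        age = entry_age + t - 1
        if age < age_cap:
            cum = np.cumsum(matrices[age - a0], axis=1)
            u = rng.random(len(state))
            active = ~exited
            new_state = state.copy()
            for s in np.unique(state[active]):
                sel = active & (state == s)
                new_state[sel] = np.searchsorted(cum[s], u[sel], side="right")
            state = new_state
        if entry_age + t >= age_cap:
            exited |= state != dead
        trace[t, :n] = np.bincount(state[~exited], minlength=n)
        trace[t, n] = exited.sum()
    return trace
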