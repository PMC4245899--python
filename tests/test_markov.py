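"""State space, transition-matrix assembly and cohort recursion."""

import numpy as np
import pytest

from conftest import random_transition_tables
from pacea.errors import ValidationError
from pacea.markov import (
    TransitionTables,
    assemble_matrix_stack,
    compute_transition_tables,
    half_cycle_corrected_person_years,
    life_years_summary,
    microsimulate,
    run_cohort,
)
from pacea.states import (
    DISEASES,
    build_state_space,
    diseased_main_state_count,
    main_state_count,
)


class TestStateSpace:
    def test_total_and_main_state_counts(self, space):
        assert space.n_states == 33
        assert main_state_count(space) == 17
        assert diseased_main_state_count(space) == 15

    def test_dead_is_last_and_unique(self, space):
        assert space.names[-1] == "DEAD"
        assert space.names.count("DEAD") == 1
        assert space.dead_index == 32

    def test_ordering_by_condition_count(self, space):
        counts = [bin(int(m)).count("1") for m in space.masks[:-1]]
        assert counts == sorted(counts)
        # not-depressed precedes depressed within each subset
        assert space.names[0] == "AT_RISK|nodep" and space.names[1] == "AT_RISK|dep"

    def test_index_round_trip(self, space):
        for s in range(space.n_states - 1):
            assert space.state_index(int(space.masks[s]), bool(space.depressed[s])) == s


def zero_tables(ages, dep=0.0):
    n = len(ages)
    return TransitionTables(
        ages=np.asarray(ages, float),
        p_death=np.zeros((n, 16)),
        p_inc=np.zeros((n, 4)),
        dep_prev=np.full((n, 16), dep),
        mean_cost=np.zeros((n, 33)),
    )


class TestAssembleMatrix:
    def test_zero_hazards_freeze_condition_sets(self, space):
        # with all hazards zero nobody changes condition set or dies; the
        # memoryless depression split still reassigns within each subset,
        # so the identity holds exactly on the not-depressed rows and on
        # the 17 main (condition-level) states
        M = assemble_matrix_stack(zero_tables([50.0]), space)[0]
        for s in range(space.n_states - 1):
            if not space.depressed[s]:
                assert M[s, s] == pytest.approx(1.0, abs=1e-15)
        for m in range(16):
            i_no, i_dep = space.alive_indices(m)
            for src in (i_no, i_dep):
                assert M[src, i_no] + M[src, i_dep] == pytest.approx(1.0, abs=1e-15)
        assert M[space.dead_index, space.dead_index] == 1.0

    def test_rows_sum_to_one_for_random_inputs(self, space):
        rng = np.random.default_rng(0)
        for _ in range(10):
            tables = random_transition_tables(rng, np.arange(40.0, 45.0))
            mult = rng.uniform(0.5, 1.0, size=(5, 4))
            M = assemble_matrix_stack(tables, space, incidence_multipliers=mult)
            np.testing.assert_allclose(M.sum(axis=2), 1.0, atol=1e-12)
            assert M.min() >= 0.0

    def test_intervention_scales_at_risk_incidence(self, space, truth_models):
        tables = compute_transition_tables(truth_models.mean_draw(), False, 1, np.arange(50.0, 55.0), space)
        m = np.full((5, 4), 0.9)
        M0 = assemble_matrix_stack(tables, space)
        M1 = assemble_matrix_stack(tables, space, incidence_multipliers=m)
        src = space.state_index(0, False)
        for j, d in enumerate(DISEASES):
            dst = space.alive_indices(1 << j)
            flow0 = M0[:, src, dst].sum(axis=1)
            flow1 = M1[:, src, dst].sum(axis=1)
            np.testing.assert_allclose(flow1, 0.9 * flow0, rtol=1e-12)
        # rows from diseased states are untouched
        sick = space.state_index(1, False)
        np.testing.assert_allclose(M0[:, sick, :], M1[:, sick, :], rtol=0, atol=0)

    def test_irreversibility_of_condition_sets(self, space):
        rng = np.random.default_rng(1)
        tables = random_transition_tables(rng, np.arange(60.0, 62.0))
        M = assemble_matrix_stack(tables, space)
        for s in range(space.n_states - 1):
            for dst in range(space.n_states - 1):
                if M[0, s, dst] > 0:
                    src_mask, dst_mask = int(space.masks[s]), int(space.masks[dst])
                    assert src_mask & dst_mask == src_mask  # superset only
                    gained = bin(dst_mask ^ src_mask).count("1")
                    assert gained <= 1  # at most one new condition per cycle

    def test_out_of_range_probability_names_cell(self, space):
        tables = zero_tables([50.0])
        tables.p_death[0, 0] = 1.5
        with pytest.raises(ValidationError, match="DEAD|probability"):
            assemble_matrix_stack(tables, space)


def two_state_matrices(p, n_ages=60):
    """Toy alive->dead chain embedded as an (n_ages, 2, 2) stack."""
    M = np.zeros((n_ages, 2, 2))
    M[:, 0, 0] = 1 - p
    M[:, 0, 1] = p
    M[:, 1, 1] = 1.0
    return M


class TestRunCohort:
    def test_geometric_decay_closed_form(self):
        p = 0.23
        M = two_state_matrices(p)
        trace = run_cohort(np.array([1.0, 0.0]), M, np.arange(40, 100), 40, n_cycles=15)
        alive = trace.occupancy[:, 0]
        np.testing.assert_allclose(alive, (1 - p) ** np.arange(16), rtol=1e-12)

    def test_dead_cohort_stays_dead(self):
        M = two_state_matrices(0.5)
        trace = run_cohort(np.array([0.0, 7.0]), M, np.arange(40, 100), 40, n_cycles=10)
        np.testing.assert_allclose(trace.occupancy[:, 1], 7.0)
        assert trace.occupancy[:, 0].max() == 0.0

    def test_occupancy_conserved_every_cycle(self, space, truth_models):
        ages = np.arange(18.0, 100.0)
        tables = compute_transition_tables(truth_models.mean_draw(), True, 3, ages, space)
        M = assemble_matrix_stack(tables, space)
        init = np.zeros(33)
        init[space.state_index(0, False)] = 1000.0
        trace = run_cohort(init, M, ages, 60, n_cycles=70)
        totals = trace.occupancy.sum(axis=1)  # states + EXITED bucket
        np.testing.assert_allclose(totals, 1000.0, atol=1e-6)
        dead = trace.occupancy[:, space.dead_index]
        assert np.all(np.diff(dead) >= -1e-9)  # absorbing, non-decreasing

    def test_age_cap_exits_whole_cohort(self, space, truth_models):
        ages = np.arange(18.0, 100.0)
        tables = compute_transition_tables(truth_models.mean_draw(), False, 1, ages, space)
        M = assemble_matrix_stack(tables, space)
        init = np.zeros(33)
        init[0] = 100.0
        trace = run_cohort(init, M, ages, 60, n_cycles=70)
        final = trace.occupancy[-1]
        alive = final[:32].sum()
        assert alive == pytest.approx(0.0, abs=1e-9)  # all dead or exited at 100
        assert final[space.dead_index] + final[33] == pytest.approx(100.0, abs=1e-6)


class TestPersonYears:
    def test_constant_occupancy(self):
        occ = np.tile(np.arange(33.0), (6, 1))
        py = half_cycle_corrected_person_years(occ)
        np.testing.assert_allclose(py, occ[1:])

    def test_single_cycle_death_gives_half_year(self):
        occ = np.zeros((2, 33))
        occ[0, 0] = 1.0
        occ[1, 32] = 1.0
        py = half_cycle_corrected_person_years(occ)
        assert py[0, 0] == pytest.approx(0.5)

    def test_linear_decline_triangle_area(self):
        occ = np.zeros((11, 33))
        occ[:, 0] = np.linspace(1.0, 0.0, 11)
        py = half_cycle_corrected_person_years(occ)
        assert py[:, 0].sum() == pytest.approx(5.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            half_cycle_corrected_person_years(np.zeros((1, 33)))


class TestLifeYearsSummary:
    def test_hand_worked_three_cycle_toy(self, space):
        py = np.zeros((3, 33))
        i_ar = space.state_index(0, False)
        i_dm = space.state_index(1, False)
        i_dm_dep = space.state_index(1, True)
        i_dual = space.state_index(3, False)
        py[:, i_ar] = [0.8, 0.6, 0.5]
        py[:, i_dm] = [0.1, 0.2, 0.2]
        py[:, i_dm_dep] = [0.05, 0.1, 0.1]
        py[:, i_dual] = [0.0, 0.05, 0.1]
        out = life_years_summary(py, entrants=1.0, space=space)
        assert out["disease_free"] == pytest.approx(1900.0)
        assert out["single"] == pytest.approx((0.5 + 0.25) * 1000)
        assert out["dual"] == pytest.approx(150.0)
        assert out["triple"] == out["quadruple"] == 0.0
        assert out["depressed"] == pytest.approx(250.0)
        assert out["total"] == pytest.approx(1900 + 750 + 150)

    def test_no_disease_transitions_all_disease_free(self, space):
        M = assemble_matrix_stack(zero_tables(np.arange(50.0, 55.0)), space)
        init = np.zeros(33)
        init[0] = 10.0
        trace = run_cohort(init, M, np.arange(50, 55), 50, n_cycles=4)
        py = half_cycle_corrected_person_years(trace.occupancy)
        out = life_years_summary(py, entrants=10.0, space=space)
        assert out["disease_free"] == pytest.approx(out["total"])
        assert out["single"] == out["depressed"] == 0.0


class TestMicrosimulationOracle:
    def test_reduced_model_cohort_vs_microsim(self, space):
        # 5-state reduced model: at-risk, DM, CHD, DM+CHD, DEAD
        rng = np.random.default_rng(7)
        n_cycles, N = 30, 20_000
        M = np.zeros((n_cycles, 5, 5))
        M[:, 0] = [0.90, 0.04, 0.03, 0.0, 0.03]
        M[:, 1] = [0.0, 0.90, 0.0, 0.05, 0.05]
        M[:, 2] = [0.0, 0.0, 0.89, 0.05, 0.06]
        M[:, 3] = [0.0, 0.0, 0.0, 0.91, 0.09]
        M[:, 4] = [0.0, 0.0, 0.0, 0.0, 1.0]
        init = np.array([float(N), 0, 0, 0, 0])
        trace = run_cohort(init, M, np.arange(50, 80), 50, n_cycles=n_cycles)
        micro = microsimulate(init.astype(int), M, np.arange(50, 80), 50, n_cycles, rng)
        for t in range(1, n_cycles + 1):
            p = trace.occupancy[t, :5] / N
            se = np.sqrt(np.maximum(p * (1 - p) / N, 1e-12)) * N
            diff = np.abs(micro[t, :5] - trace.occupancy[t, :5])
            assert np.all(diff <= 3 * se + 3)


class TestMonotonicity:
    def test_higher_incidence_lowers_disease_free_years(self, space, truth_models, config):
        from pacea.config import build_truth_models

        ages = np.arange(18.0, 100.0)
        import copy

        cfg_hi = copy.deepcopy(config)
        cfg_hi["weibull_incidence"]["DM"]["log_scale"] += 0.5
        out = {}
        for name, models in (("base", truth_models), ("hi", build_truth_models(cfg_hi))):
            tables = compute_transition_tables(models.mean_draw(), False, 2, ages, space)
            M = assemble_matrix_stack(tables, space)
            init = np.zeros(33)
            init[0] = 1000.0
            trace = run_cohort(init, M, ages, 55, n_cycles=70)
            py = half_cycle_corrected_person_years(trace.occupancy)
            out[name] = life_years_summary(py, 1000.0, space)["disease_free"]
        assert out["hi"] < out["base"]
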