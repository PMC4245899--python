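"""Shared fixtures: default configuration objects and small synthetic data."""

import numpy as np
import pytest

from pacea.config import (
    build_activity_distribution,
    build_demographics,
    build_relative_risks,
    build_truth_models,
    build_utilities,
    load_default_config,
)
from pacea.intervention import InterventionSpec
from pacea.states import build_state_space


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def truth_models(config):
    return build_truth_models(config)


@pytest.fixture(scope="session")
def demographics(config):
    return build_demographics(config)


@pytest.fixture(scope="session")
def activity(config):
    return build_activity_distribution(config)


@pytest.fixture(scope="session")
def relative_risks(config):
    return build_relative_risks(config)


@pytest.fixture(scope="session")
def utilities(config):
    return build_utilities(config)


@pytest.fixture(scope="session")
def space():
    return build_state_space()


@pytest.fixture
def spec():
    return InterventionSpec()


@pytest.fixture(scope="session")
def small_registry(truth_models, demographics):
    """A 10k-person registry with 5 years of follow-up (fast profile)."""
    from pacea.registry import generate_cohort, simulate_event_histories

    cohort = generate_cohort(10_000, 20140130, demographics)
    return simulate_event_histories(cohort, truth_models, horizon=5.0, seed=20140131)


def random_transition_tables(rng, ages, n_masks=16, n_dis=4, n_states=33):
    """Random but structurally valid TransitionTables for property tests."""
    from pacea.markov import TransitionTables

    n_ages = len(ages)
    return TransitionTables(
        ages=np.asarray(ages, dtype=float),
        p_death=rng.uniform(0.0, 0.4, size=(n_ages, n_masks)),
        p_inc=rng.uniform(0.0, 0.2, size=(n_ages, n_dis)),
        dep_prev=rng.uniform(0.0, 1.0, size=(n_ages, n_masks)),
        mean_cost=rng.uniform(0.0, 5000.0, size=(n_ages, n_states)),
    )
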