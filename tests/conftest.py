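import numpy as np
import pytest

from tripletsl.behavior_sim import CohortSpec, simulate_cohort
from tripletsl.response_scoring import score_bundle
from tripletsl.sl_metrics import compute_measures, composite_scores
from tripletsl.task_design import DEFAULT_TASKS, build_triplet_inventory


@pytest.fixture
def visual_config():
    return DEFAULT_TASKS["letter"]


@pytest.fixture
def auditory_config():
    return DEFAULT_TASKS["syllable"]


@pytest.fixture
def stimulus_ids():
    return [f"s{i:02d}" for i in range(12)]


@pytest.fixture
def inventory(stimulus_ids):
    return build_triplet_inventory(stimulus_ids, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-child cohort with every task completed, shared across tests."""
    spec = CohortSpec(
        n_per_group={"TD": 6, "ASD": 6}, missing_task_prob=0.0, recall_prob=1.0, seed=11
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    return score_bundle(small_cohort)


@pytest.fixture(scope="session")
def small_measures(small_cohort, small_scored):
    m = compute_measures(small_scored, small_cohort)
    m, dom = composite_scores(m, small_cohort.configs)
    return m, dom


@pytest.fixture
def rng():
    return np.random.default_rng(123)
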