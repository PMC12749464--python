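import numpy as np
import pytest
from hypothesis import settings

from partnerseq import om, sequences, simulate

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def cohort():
    """Moderate synthetic cohort reused across tests (fixed seed)."""
    return simulate.simulate_cohort(simulate.GeneratorConfig(n=1000, seed=7))


@pytest.fixture(scope="session")
def cohort_sequences(cohort):
    return simulate.latent_sequence_set(cohort)


@pytest.fixture(scope="session")
def cohort_scheme(cohort_sequences):
    rates = om.estimate_transition_rates(cohort_sequences)
    return om.trate_costs(rates)


@pytest.fixture(scope="session")
def cohort_distances(cohort_sequences, cohort_scheme):
    return om.pairwise_matrix(cohort_sequences, cohort_scheme)


def histories_of(cohort):
    """Convert a simulated cohort's record tables to PersonHistory objects."""
    return sequences.histories_from_frames(cohort.persons, cohort.marriages)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
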