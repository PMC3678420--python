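import numpy as np
import pytest

from pmdtune import (
    SessionConfig,
    Task,
    align_and_window,
    bin_rates,
    default_ensemble,
    indicator_samples,
    simulate_session,
)


@pytest.fixture(scope="session")
def small_ensemble():
    """2 neurons per category, strong preset."""
    return default_ensemble(2, 2, 2, 2, effect="strong", seed=11)


@pytest.fixture(scope="session")
def reach_session(small_ensemble):
    return simulate_session(
        SessionConfig(task=Task.REACH, neurons=small_ensemble, rng_seed=101, trials_per_action=10)
    )


@pytest.fixture(scope="session")
def grasp_session(small_ensemble):
    return simulate_session(
        SessionConfig(task=Task.GRASP, neurons=small_ensemble, rng_seed=102, trials_per_action=10)
    )


@pytest.fixture(scope="session")
def reach_binned(reach_session):
    return bin_rates(align_and_window(reach_session))


@pytest.fixture(scope="session")
def session_pair_indicators(reach_session, grasp_session):
    out = []
    for session in (reach_session, grasp_session):
        aligned = align_and_window(session)
        out.append(indicator_samples(aligned))
    return tuple(out)


def simulate_pair(seed, counts=(7, 5, 9, 10), trials=(25, 50), effect="strong"):
    """Seeded session pair sharing one ensemble (helper for recovery tests)."""
    ensemble = default_ensemble(*counts, effect=effect, seed=seed)
    reach = simulate_session(
        SessionConfig(
            task=Task.REACH, neurons=ensemble, rng_seed=seed + 1, trials_per_action=trials[0]
        )
    )
    grasp = simulate_session(
        SessionConfig(
            task=Task.GRASP, neurons=ensemble, rng_seed=seed + 2, trials_per_action=trials[1]
        )
    )
    return ensemble, reach, grasp
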