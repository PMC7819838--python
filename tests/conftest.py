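import dataclasses

import numpy as np
import pytest

from neosleep import (
    Bout,
    SimConfig,
    SubjectCovariates,
    enforce_min_state_rule,
    extract_bouts,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def quiet_config(default_config) -> SimConfig:
    """Default generator without sensory events (unperturbed chain)."""
    return dataclasses.replace(default_config, lance_prob=0.0, non_noxious_prob=0.0)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    return simulate_cohort(default_config, 60, seed=11)


@pytest.fixture(scope="session")
def cohort_bouts(small_cohort):
    bouts = []
    for h in small_cohort.hypnograms:
        h.states = enforce_min_state_rule(h.states)
        bouts.extend(extract_bouts(h))
    return bouts


def make_bout(
    state="AS",
    duration=5.0,
    observed=True,
    next_state="QS",
    onset=0.5,
    subject="s1",
    **cov,
) -> Bout:
    return Bout(
        subject_id=subject,
        state=state,
        onset_min=onset,
        duration_min=duration,
        onset_captured=True,
        offset_captured=observed,
        next_state=next_state if observed else None,
        covariates=SubjectCovariates(**cov),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
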