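import numpy as np
import pytest

from skillnet import CohortConfig, generate_cohort
from skillnet.io import PipelineConfig, build_networks, compute_session_features

#: Small study used across tests: 8 participants in two blocks of four,
#: three sessions, short trials so the suite stays fast.
TINY_KW = dict(
    n_participants=8,
    n_sessions=3,
    n_trials=2,
    trial_duration=0.4,
    tasks=("peg_transfer",),
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(CohortConfig(**TINY_KW))


@pytest.fixture(scope="session")
def noise_free_cohort():
    return generate_cohort(CohortConfig(**{**TINY_KW, "noise_sd": 0.0}))


def cohort_networks(cohort, **cfg_kw):
    """Features and per-(task, hand) session networks for a cohort."""
    cfg = PipelineConfig(**cfg_kw)
    feats = compute_session_features(cohort.emg_trials, cohort.mvc_table, cfg)
    nets = {
        slot: {s: net for s, (_, net) in per_session.items()}
        for slot, per_session in build_networks(feats, cfg).items()
    }
    return feats, nets


@pytest.fixture(scope="session")
def noise_free_networks(noise_free_cohort):
    return cohort_networks(noise_free_cohort)


def rng_for(seed):
    return np.random.default_rng(seed)
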