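"""Shared fixtures: synthetic studies and trained hybrid models.

The expensive fixtures (trained fits) are session-scoped so the recovery,
analysis and residual tests share one training run per scenario.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybridferm.model import ANNParameters
from hybridferm.plant import (
    BatchConditions,
    constant_kinetics,
    default_true_kinetics,
    generate_study,
    simulate_true_batch,
)
from hybridferm.training import TrainingConfig, partition_by_acetate, train

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# identification settings shared by the recovery experiments
RECOVERY_CONFIG = TrainingConfig(n_restarts=10, max_iterations=300, patience=25, seed=11)


def split_partitions(records):
    train_b = [b for b in records if b.partition == "train"]
    val_b = [b for b in records if b.partition == "validation"]
    return train_b, val_b


@pytest.fixture(scope="session")
def kinetics():
    return default_true_kinetics()


@pytest.fixture(scope="session")
def study_noiseless_doe(kinetics):
    """24-batch noiseless study: the 23-run Doehlert campaign plus the
    investigative batch."""
    return generate_study(kinetics, seed=3, noise=False, doe_only=True)


@pytest.fixture(scope="session")
def study_noisy_doe(kinetics):
    return generate_study(kinetics, seed=3, noise=True, doe_only=True)


@pytest.fixture(scope="session")
def study_full_noisy(kinetics):
    """53-batch noisy study emulating the complete campaign."""
    return generate_study(kinetics, seed=3, noise=True)


@pytest.fixture(scope="session")
def fit_noiseless(study_noiseless_doe):
    tr, val = split_partitions(study_noiseless_doe)
    return train(5, tr, val, RECOVERY_CONFIG)


@pytest.fixture(scope="session")
def fit_noisy(study_noisy_doe):
    tr, val = split_partitions(study_noisy_doe)
    return train(5, tr, val, RECOVERY_CONFIG)


@pytest.fixture(scope="session")
def fit_hm2(kinetics):
    """Hybrid model trained on the noiseless full study with the
    acetate-based (all-regions) partitioning."""
    full = generate_study(kinetics, seed=3, noise=False)
    partition_by_acetate(full, seed=17)
    tr, val = split_partitions(full)
    return train(5, tr, val, RECOVERY_CONFIG)


@pytest.fixture()
def zero_feed_record():
    """No-feed batch under constant growth mu = 0.1 1/h: the biomass balance
    reduces to pure exponential growth."""
    return simulate_true_batch(
        BatchConditions(X_ind=10.0, induction_duration=7.0),
        constant_kinetics(mu=0.1),
        step=0.05,
        X0=10.0,
        feed_base=0.0,
    )


@pytest.fixture()
def constant_mu_params():
    """Zero-weight network emitting constant rates via the output bias:
    mu = 0.1 1/h, v_px = 0, a_base = 0 (identity output scaling)."""
    return ANNParameters(
        w1=np.zeros((1, 5)), b1=np.zeros(1),
        w2=np.zeros((3, 1)), b2=np.array([0.1, 0.0, 0.0]),
        input_offset=np.zeros(5), input_scale=np.ones(5),
        output_offset=np.zeros(3), output_scale=np.ones(3),
    )


def r2_score(measured, predicted):
    measured = np.asarray(measured, float)
    predicted = np.asarray(predicted, float)
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    return 1.0 - float(np.sum((measured - predicted) ** 2)) / ss_tot
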