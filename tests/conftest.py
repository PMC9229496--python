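"""Shared fixtures: simulated recordings and prepared exemplar signals.

Everything is generated at test time from the parametric simulator with a
fixed seed; no data files are stored.
"""

import numpy as np
import pytest

from gaitstage.synthesis import (
    SignalConfig,
    build_synthetic_dataset,
    normal_gait,
    parkinsonian_gait,
    prepare_exemplars,
    simulate_gait,
)


@pytest.fixture(scope="session")
def normal_series():
    return simulate_gait(normal_gait(seed=22))


@pytest.fixture(scope="session")
def pd_series():
    return simulate_gait(parkinsonian_gait(seed=22))


@pytest.fixture(scope="session")
def exemplars(pd_series, normal_series):
    """(parkinsonian_triple, normal_triple) on a shared normalized grid."""
    return prepare_exemplars(pd_series, normal_series, SignalConfig())


@pytest.fixture(scope="session")
def small_dataset(exemplars):
    """Labeled synthetic feature table at a small omega count (fast)."""
    trip_p, trip_n = exemplars
    return build_synthetic_dataset(trip_p, trip_n, n_combinations=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(22)
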