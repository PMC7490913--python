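import numpy as np
import pytest

from hisskit.domain import RegimeTable
from hisskit.experts import (
    default_committee,
    majority_vote,
    possibility_labels,
    score_cohort,
)
from hisskit.io import features_from_frame, records_to_frame
from hisskit.sfrp import CohortConfig, NoiseConfig, generate_cohort


@pytest.fixture(scope="session")
def table() -> RegimeTable:
    return RegimeTable.default()


@pytest.fixture(scope="session")
def quiet_cohort():
    """Zero-noise 100-patient cohort scored by a noiseless committee."""
    config = CohortConfig(noise=NoiseConfig.quiet(), rng_seed=1)
    records = generate_cohort(100, config)
    committee = default_committee(intra_noise=0.0)
    matrix = score_cohort(records, committee, np.random.default_rng(7))
    X = features_from_frame(records_to_frame(records))
    y = np.array([majority_vote(row) for row in matrix.originals()])
    U = np.array([possibility_labels(row) for row in matrix.originals()])
    return records, X, y, U


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise 100-patient cohort with the default (noisy) committee."""
    config = CohortConfig(rng_seed=3)
    records = generate_cohort(100, config)
    committee = default_committee()
    matrix = score_cohort(records, committee, np.random.default_rng(11))
    X = features_from_frame(records_to_frame(records))
    y = np.array([majority_vote(row) for row in matrix.originals()])
    return records, X, y, matrix
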