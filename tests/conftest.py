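import numpy as np
import pytest

from parcelmark.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact null cohort (60 parcels, 2 batches) with time series."""
    config = CohortConfig(
        n_cases=20,
        n_controls_per_batch=(10, 10),
        n_parcels=60,
        n_subcortical=10,
        n_timepoints=100,
        seed=11,
    )
    samples, timeseries = generate_cohort(config)
    return config, samples, timeseries


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
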