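import numpy as np
import pandas as pd
import pytest

from gradstates.prep import ParcelTimeSeries
from gradstates.synthetic import SyntheticCohortConfig, default_network_labels


def make_timeseries(data: np.ndarray, tr: float = 2.0,
                    subject_id: str = "sub") -> ParcelTimeSeries:
    """Wrap a raw matrix in a ParcelTimeSeries with default network labels."""
    n_parcels = data.shape[1]
    parcels = pd.DataFrame({
        "parcel_id": [f"p{i:03d}" for i in range(n_parcels)],
        "network": list(default_network_labels(n_parcels)),
    })
    return ParcelTimeSeries(subject_id=subject_id, data=data, tr_seconds=tr,
                            parcels=parcels)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_config():
    """Small, fast cohort configuration used across unit tests."""
    return SyntheticCohortConfig(n_per_group=3, n_parcels=21, n_timepoints=120,
                                 seed=11)


@pytest.fixture
def random_timeseries(rng):
    return make_timeseries(rng.standard_normal((120, 14)))
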