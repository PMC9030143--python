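import numpy as np
import pytest

from longconn.cohort import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group cohort with a strong static effect; fast to classify."""
    spec = CohortSpec(roi_count=12, frames_per_scan=60,
                      group_sizes={"NC": 10, "AD": 10}, edge_effect=0.8,
                      progression_rate=0.0, affected_edge_fraction=0.5,
                      subject_noise_sd=0.0, seed=7)
    return simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
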