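import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import linear_sum_assignment

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from enterosig.prep import tss_normalize
from enterosig.synthetic import make_metadata, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Standard synthetic cohort: 74 samples, 4 planted subcommunities,
    300 features, multinomial depth 1e5."""
    return simulate_cohort(seed=5)


@pytest.fixture(scope="session")
def cohort_tss(cohort):
    return tss_normalize(cohort.mag_matrix)


@pytest.fixture(scope="session")
def metadata75():
    """Full 25-animal x 3-timepoint design (no dropped sample)."""
    return make_metadata(13, 12, drop=0, seed=0)


def matched_cosine(H: np.ndarray, H_ref: np.ndarray) -> np.ndarray:
    """Per-factor cosine similarity under the optimal factor matching."""
    A = H / np.linalg.norm(H, axis=1, keepdims=True)
    B = H_ref / np.linalg.norm(H_ref, axis=1, keepdims=True)
    S = A @ B.T
    ri, ci = linear_sum_assignment(-S)
    return S[ri, ci]
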