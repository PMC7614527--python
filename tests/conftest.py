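import numpy as np
import pytest

import statedyn as sd


@pytest.fixture(scope="session")
def truth_k3():
    """Well-separated 3-state ground truth on 6 channels."""
    return sd.sample_ground_truth(3, 6, 0.85, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort shared by several statistics tests."""
    spec = sd.CohortSpec(
        group_sizes={"noncarrier": 40, "presymptomatic": 40, "symptomatic": 25},
        n_converters=6,
        T_per_scan=200,
        n_channels=8,
        n_states=4,
        seed=21,
    )
    return sd.simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def posterior_fo(cohort, subjects=None):
    """Fractional occupancies under the generating model for a cohort.

    The ground-truth model lives in raw observation space, so posteriors are
    computed on the raw (unstandardized) time courses.
    """
    from statedyn.hmm import forward_backward
    from statedyn.metrics import fractional_occupancy

    subs = cohort.subjects if subjects is None else subjects
    return np.array(
        [
            fractional_occupancy(forward_backward(cohort.ground_truth, s.timecourse))
            for s in subs
        ]
    )
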