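import numpy as np
import pytest

from twingrowth import CohortConfig, TruthParams, simulate_cohort
from twingrowth.params import GrowthTruth


@pytest.fixture(scope="session")
def default_truth():
    return TruthParams()


@pytest.fixture(scope="session")
def small_cohort(default_truth):
    """30 twin pairs, 5 trials/condition, full design complexity."""
    cfg = CohortConfig(n_families=30, trials_per_condition=5, seed=123)
    return cfg, simulate_cohort(cfg, default_truth)


def intercept_only_truth(shares=(0.29, 0.03, 0.03, 0.65), nu=8.0, mean=2.5):
    """Behavior truth whose intercept-only variance decomposition equals
    the given (wave, individual, family, residual) shares of unit total."""
    v_w, v_u, v_v, v_e = shares
    sigma = np.sqrt(v_e * (nu - 2.0) / nu)
    beh = GrowthTruth(
        beta=(0.0, 0.0, 0.0), tau_u=(0.0, 0.0, 0.0), tau_v=(0.0, 0.0, 0.0),
        sigma=sigma, nu=nu, gamma=(mean, 0.0, 0.0), tau_w=np.sqrt(v_w),
        tau_u_base=np.sqrt(v_u), tau_v_base=np.sqrt(v_v),
    )
    base = TruthParams()
    return TruthParams(outcomes={**base.outcomes, "behavior": beh})
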