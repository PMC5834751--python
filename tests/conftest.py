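import pytest

from goalshape.cohort_sim import SimParams, simulate_cohort


def small_cohort_params(seed: int = 11, n: int = 15) -> SimParams:
    return SimParams(n_participants=n, rng_seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared across read-only tests."""
    params = small_cohort_params()
    log, truth = simulate_cohort(params)
    return params, log, truth


def full_compliance_params(seed: int = 5, n: int = 10, blocks: int = 2) -> SimParams:
    """Everyone answers everything; commitment certain; one re-enrollment path."""
    reenroll = tuple(1.0 if i < blocks - 1 else 0.0 for i in range(6))
    return SimParams(
        n_participants=n,
        thu_sun_response_prob=1.0,
        confidence_response_prob=1.0,
        runin_response_prob=1.0,
        enroll_optin_prob=1.0,
        commitment_prob=1.0,
        plan_prob_schedule=(1.0,),
        reenroll_probs=reenroll,
        rng_seed=seed,
    )
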