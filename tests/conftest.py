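from dataclasses import replace

import pytest

import contextprob as cp


@pytest.fixture(scope="session")
def exp1():
    return cp.build_design(1)


@pytest.fixture(scope="session")
def exp2():
    return cp.build_design(2)


@pytest.fixture(scope="session")
def urd_variance_spec():
    """URD-gamma with variance-weighted uncertainty (the generative truth
    used for the qualitative cohort studies)."""
    return replace(cp.get_model_spec("URD-g"), uncertainty_stat="variance")


@pytest.fixture(scope="session")
def acceptance_cohort(exp1, urd_variance_spec):
    """34 simulated subjects under the study conditions: URD-gamma truth
    (gamma 0.6, variance-weighted uncertainty, 10-trial window), estimate
    noise SD 0.05, softmax temperature 10."""
    return cp.simulate_cohort(
        exp1,
        34,
        urd_variance_spec,
        cp.ModelParams(gamma=0.6, n_past=10),
        master_seed=20260101,
        noise_sd=0.05,
    )


@pytest.fixture(scope="session")
def small_cohort(exp1):
    """A fast 6-subject cohort (plain URD truth) for structural tests."""
    return cp.simulate_cohort(
        exp1,
        6,
        cp.get_model_spec("URD"),
        cp.ModelParams(n_past=10),
        master_seed=7,
        noise_sd=0.05,
    )
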