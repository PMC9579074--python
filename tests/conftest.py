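import pytest

from semlrt import (
    ConditionSpec,
    correct_spec,
    default_population,
    misspecified_spec,
    null_spec,
    run_condition,
)


@pytest.fixture(scope="session")
def pop():
    return default_population()


@pytest.fixture(scope="session")
def specs():
    return {
        "correct": correct_spec(),
        "misspecified": misspecified_spec(),
        "null": null_spec(),
    }


@pytest.fixture(scope="session")
def normal_mc(pop):
    """Shared Monte Carlo batch: multivariate normal data, correct model,
    N = 1000, 500 replications.  Used by the asymptotic-robustness and
    chi-square distribution checks."""
    cond = ConditionSpec(
        source="normal", kurtosis=3.0, n=1000, specification="correct",
        reps=500, seed=20260901,
    )
    return run_condition(cond, pop)
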