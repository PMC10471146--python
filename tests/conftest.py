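import pytest

from ptmc_cea import (
    ModelBundle,
    calibrate_costs,
    load_cost_schedule,
    load_parameters,
    load_strategy,
)
from ptmc_cea.report import PUBLISHED_COST_TARGETS


@pytest.fixture(scope="session")
def params():
    return load_parameters("table1_verbatim")


@pytest.fixture(scope="session")
def params_canonical():
    return load_parameters("text_canonical")


@pytest.fixture(scope="session")
def as_strategy():
    return load_strategy("AS")


@pytest.fixture(scope="session")
def es_strategy():
    return load_strategy("ES")


@pytest.fixture(scope="session")
def costs():
    return load_cost_schedule()


@pytest.fixture(scope="session")
def bundle(params, es_strategy, as_strategy, costs):
    """Base-case (age 40, 40 cycles) bundle with the uncalibrated schedule."""
    return ModelBundle(params, es_strategy, as_strategy, costs)


@pytest.fixture(scope="session")
def calibrated_bundle(params, es_strategy, as_strategy, costs):
    """Base-case bundle with costs calibrated to the published lifetime totals."""
    probe = ModelBundle(params, es_strategy, as_strategy, costs)
    result = calibrate_costs(
        costs,
        (PUBLISHED_COST_TARGETS["ES"], PUBLISHED_COST_TARGETS["AS"]),
        lambda c: tuple(x[0] for x in probe.run_pair(costs=c)),
    )
    assert result.converged
    return ModelBundle(params, es_strategy, as_strategy, result.schedule)
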