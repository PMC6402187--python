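import pytest

from trialflow import (
    CostModel,
    default_scenarios,
    run_flow,
    scenario_1,
    scenario_2,
    scenario_3,
    scenario_4,
)


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def flows(scenarios):
    return {s.name: run_flow(s) for s in scenarios}


@pytest.fixture(scope="session")
def s1():
    return scenario_1()


@pytest.fixture(scope="session")
def s2():
    return scenario_2()


@pytest.fixture(scope="session")
def s3():
    return scenario_3()


@pytest.fixture(scope="session")
def s4():
    return scenario_4()


@pytest.fixture(scope="session")
def cost_model():
    return CostModel()
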