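import pytest

from gpcontract import Parameters, ScenarioConfig


@pytest.fixture(scope="session")
def default_params() -> Parameters:
    return Parameters()


@pytest.fixture(scope="session")
def all_on() -> ScenarioConfig:
    return ScenarioConfig(hcs=1, wdp=1, hec=1, et=1, jtp=1, ii=1)


@pytest.fixture(scope="session")
def reference_params() -> Parameters:
    from gpcontract import reference_calibration

    return reference_calibration()
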