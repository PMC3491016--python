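import pytest

from hivcea import ModelParameters, default_bins, run_base_case


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def bins(params):
    return default_bins(params)


@pytest.fixture(scope="session")
def base_summary(params):
    """One shared full base-case run (deterministic)."""
    return run_base_case(params)
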