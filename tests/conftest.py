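import pytest

from pancea import CE_CT, CE_MR_CT, default_params, run_base_case


@pytest.fixture(scope="session")
def params():
    """Base-case parameter set with the default structural flags."""
    return default_params()


@pytest.fixture(scope="session")
def base_case(params):
    """(results-by-strategy-name, CE-MR/CT-vs-CE-CT comparison)."""
    return run_base_case(params)
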