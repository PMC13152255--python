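import pytest
from hypothesis import HealthCheck, settings

from sgecurate import datasets

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_records():
    return datasets.load_discordant_variants()


@pytest.fixture(scope="session")
def table1_frame():
    return datasets.discordant_variants_frame()


@pytest.fixture(scope="session")
def table2_records():
    return datasets.load_concordant_vus()


@pytest.fixture(scope="session")
def table2_frame():
    return datasets.concordant_vus_frame()
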