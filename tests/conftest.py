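import pytest

from ninescore import default_rubric, rank_systems, rate_systems, table5_fixture


@pytest.fixture(scope="session")
def rubric():
    return default_rubric()


@pytest.fixture(scope="session")
def worked_profiles():
    return table5_fixture()


@pytest.fixture(scope="session")
def worked_table(worked_profiles):
    return rank_systems(rate_systems(worked_profiles))
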